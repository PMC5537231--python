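"""Kinship-structured linear mixed models for family data.

The association model regresses subjective well-being (SWB) on a Z-scored
subcortical volume and its square, with intracranial volume, sex, age at
MRI and study as fixed covariates and a genetic-relatedness random effect:
``y ~ N(X beta, sigma2_g * K + sigma2_e * I)`` where K holds 1.0 between MZ
co-twins, 0.5 between DZ co-twins and siblings, and 0 across families.

Fitting profiles the likelihood over the heritability-like ratio
``h = sigma2_g / (sigma2_g + sigma2_e)`` after rotating the data into the
eigenbasis of K, so each candidate ratio costs a weighted least-squares
solve.  Single-coefficient tests use a Satterthwaite approximation to the
denominator degrees of freedom (with a residual-df fallback), mirroring the
convention of mainstream mixed-model software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "zscore",
    "build_kinship",
    "KinshipEigen",
    "LmmFit",
    "fit_kinship_lmm",
    "test_fixed_term",
    "test_joint_terms",
    "association_scan",
    "posthoc_battery",
    "swb_by_volume_strata",
    "two_group_anova_from_summary",
    "REGIONS",
    "BONFERRONI_ALPHA",
]

REGIONS = ["caudate", "putamen", "pallidum", "thalamus", "hippocampus",
           "amygdala", "accumbens"]
#: 7 structures x 2 hemispheres
BONFERRONI_ALPHA = 0.05 / 14

_POSTHOC_VARIANTS = ("outcome_sat", "outcome_hap", "drop_quadratic",
                     "raw_volumes", "add_age_swb", "add_symptom_score",
                     "study_interactions")


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def zscore(values) -> np.ndarray:
    """Standardize to mean 0 and (n-1 denominator) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("zscore expects a 1-D vector")
    if np.unique(x[~np.isnan(x)]).size < 2:
        raise ValueError("cannot Z-score a constant vector (zero SD)")
    mean = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    return (x - mean) / sd


def build_kinship(cohort: pd.DataFrame) -> np.ndarray:
    """Genetic-relatedness matrix over cohort rows (in row order).

    1.0 on the diagonal and between MZ co-twins; 0.5 between DZ co-twins and
    between any pair of siblings within a family; 0 across families.
    """
    if cohort["person_id"].duplicated().any():
        dup = cohort.loc[cohort["person_id"].duplicated(), "person_id"]
        raise ValueError(f"duplicated person_id: {sorted(set(dup))}")
    fam_of = cohort.groupby("person_id")["family_id"].nunique()
    if (fam_of > 1).any():
        raise ValueError("a person appears in more than one family")

    n = len(cohort)
    k = np.eye(n)
    fam = cohort["family_id"].to_numpy()
    role = cohort["zygosity_role"].to_numpy()
    order = {}
    for i in range(n):
        order.setdefault(fam[i], []).append(i)
    for idx in order.values():
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                pair = {role[i], role[j]}
                kin = 1.0 if pair == {"MZ1", "MZ2"} else 0.5
                k[i, j] = k[j, i] = kin
    return k


# ---------------------------------------------------------------------------
# mixed-model core
# ---------------------------------------------------------------------------

class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix.

    Re-used across model fits on the same rows (e.g. the 14-region scan),
    since the decomposition dominates the cost of a single fit.
    """

    def __init__(self, k: np.ndarray):
        k = np.asarray(k, float)
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        lam, u = np.linalg.eigh(k)
        if lam.min() < -1e-8 * max(1.0, lam.max()):
            raise ValueError("kinship matrix is not positive semi-definite")
        self.lam = np.clip(lam, 0.0, None)
        self.u = u
        self.n = k.shape[0]

    def rotate(self, m: np.ndarray) -> np.ndarray:
        return self.u.T @ m


@dataclass
class LmmFit:
    """ML (or REML) fit of y ~ N(X beta, sigma2_g K + sigma2_e I)."""

    beta: np.ndarray
    se: np.ndarray
    sigma2_g: float
    sigma2_e: float
    loglik: float
    n: int
    term_names: list[str]
    method: str = "ML"
    # internals retained for Satterthwaite tests
    _lam: np.ndarray = field(default=None, repr=False)
    _xt: np.ndarray = field(default=None, repr=False)
    _cov_beta: np.ndarray = field(default=None, repr=False)

    @property
    def h2_ratio(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    def term_index(self, term: str) -> int:
        try:
            return self.term_names.index(term)
        except ValueError:
            raise KeyError(f"unknown term {term!r}; have {self.term_names}")


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(x)
    if r < x.shape[1]:
        # identify aliased columns via pivoted QR on the correlation structure
        q, rm, piv = _qr_pivot(x)
        aliased = [names[j] for j in piv[r:]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: "
                         f"{aliased}")


def _qr_pivot(x):
    from scipy.linalg import qr
    q, rm, piv = qr(x, mode="economic", pivoting=True)
    return q, rm, piv


def fit_kinship_lmm(
    y,
    x,
    k=None,
    *,
    eig: KinshipEigen | None = None,
    term_names: list[str] | None = None,
    method: str = "ML",
) -> LmmFit:
    """Fit the kinship mixed model by profiled maximum likelihood.

    Either ``k`` (the kinship matrix) or a precomputed ``eig`` decomposition
    must be given.  The variance structure is profiled over the ratio
    ``h = sigma2_g / (sigma2_g + sigma2_e)`` with a bounded scalar search;
    the fixed effects are the GLS solution at the optimum.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("y and X have different lengths")
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    if len(term_names) != p:
        raise ValueError("term_names length mismatch")
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    _check_full_rank(x, term_names)
    if eig is None:
        if k is None:
            raise ValueError("provide a kinship matrix or its decomposition")
        eig = KinshipEigen(k)
    if eig.n != n:
        raise ValueError("kinship decomposition size mismatch")

    lam = eig.lam
    yt = eig.rotate(y)
    xt = eig.rotate(x)
    dfres = n - p

    def profile(h: float):
        d = h * lam + (1.0 - h)
        w = 1.0 / d
        xtw = xt * w[:, None]
        a = xtw.T @ xt
        b = xtw.T @ yt
        try:
            beta = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            return np.inf, None
        r = yt - xt @ beta
        rss = float(np.sum(r * r * w))
        logdet = float(np.sum(np.log(d)))
        if method == "ML":
            s2 = rss / n
            ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
        else:
            s2 = rss / dfres
            sign, ldxa = np.linalg.slogdet(a / s2)
            ll = -0.5 * (dfres * np.log(2 * np.pi * s2) + logdet
                         + ldxa + dfres)
        return -ll, (beta, s2, a)

    res = optimize.minimize_scalar(lambda h: profile(h)[0],
                                   bounds=(0.0, 1.0 - 1e-9),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    h = float(res.x)
    # boundary check: the profile can be monotone toward h = 0
    if profile(0.0)[0] <= res.fun + 1e-12:
        h = 0.0
    nll, (beta, s2, a) = profile(h)
    cov_beta = s2 * np.linalg.inv(a)
    se = np.sqrt(np.diag(cov_beta))
    return LmmFit(beta=beta, se=se,
                  sigma2_g=h * s2, sigma2_e=(1.0 - h) * s2,
                  loglik=-nll, n=n, term_names=list(term_names),
                  method=method, _lam=lam, _xt=xt, _cov_beta=cov_beta)


def _satterthwaite_df(fit: LmmFit, c: np.ndarray) -> float:
    """Satterthwaite denominator df for the contrast variance c' Cov(beta) c.

    Uses the delta method on the ML variance components with the expected
    Fisher information; falls back to residual df when the information is
    (near-)singular, e.g. when K = I leaves the split unidentified.
    """
    lam = fit._lam
    n = fit.n
    p = fit._xt.shape[1]
    sg, se2 = fit.sigma2_g, fit.sigma2_e
    w = sg * lam + se2          # eigenvalues of V
    if np.any(w <= 0):
        return float(n - p)
    iw = 1.0 / w
    # Fisher information of (sigma2_g, sigma2_e)
    i_gg = 0.5 * np.sum((lam * iw) ** 2)
    i_ge = 0.5 * np.sum(lam * iw * iw)
    i_ee = 0.5 * np.sum(iw * iw)
    info = np.array([[i_gg, i_ge], [i_ge, i_ee]])
    xt = fit._xt
    xtw = xt * iw[:, None]
    a = xtw.T @ xt              # X' V^-1 X
    try:
        ainv = np.linalg.inv(a)
        vcov_sigma = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(n - p)
    if np.linalg.cond(info) > 1e10:
        return float(n - p)
    g = float(c @ ainv @ c)
    ac = ainv @ c
    # dg/dsigma_i = c' A^-1 (X' V^-1 Vi V^-1 X) A^-1 c
    xac = xt @ ac
    dg_g = float(np.sum(lam * iw * iw * xac * xac))
    dg_e = float(np.sum(iw * iw * xac * xac))
    grad = np.array([dg_g, dg_e])
    denom = float(grad @ vcov_sigma @ grad)
    if denom <= 0:
        return float(n - p)
    df = 2.0 * g * g / denom
    return float(np.clip(df, 1.0, n - p))


def test_fixed_term(fit: LmmFit, term: str | int,
                    *, df_method: str = "satterthwaite"):
    """Single-coefficient F test: F = (beta/se)^2 with approximate df.

    Returns ``(F, denominator df, p)``; two-tailed by construction since the
    F statistic is the squared Wald ratio.
    """
    j = fit.term_index(term) if isinstance(term, str) else int(term)
    if not 0 <= j < len(fit.beta):
        raise KeyError(f"unknown term {term!r}")
    f = float((fit.beta[j] / fit.se[j]) ** 2)
    if df_method == "satterthwaite":
        c = np.zeros(len(fit.beta))
        c[j] = 1.0
        df = _satterthwaite_df(fit, c)
    elif df_method == "residual":
        df = float(fit.n - len(fit.beta))
    else:
        raise ValueError("df_method must be 'satterthwaite' or 'residual'")
    p = float(stats.f.sf(f, 1, df))
    return f, df, p


def test_joint_terms(fit: LmmFit, terms: list[str]):
    """Wald F test of several coefficients jointly (residual denominator df)."""
    idx = [fit.term_index(t) if isinstance(t, str) else int(t) for t in terms]
    q = len(idx)
    if q == 0:
        raise ValueError("no terms given")
    b = fit.beta[idx]
    v = fit._cov_beta[np.ix_(idx, idx)]
    f = float(b @ np.linalg.solve(v, b)) / q
    df = float(fit.n - len(fit.beta))
    p = float(stats.f.sf(f, q, df))
    return f, df, p


# ---------------------------------------------------------------------------
# association scan and post-hoc battery
# ---------------------------------------------------------------------------

def _design_for_region(
    cohort: pd.DataFrame,
    region: str,
    hemi: str,
    *,
    outcome: str = "swb",
    standardize: bool = True,
    drop_quadratic: bool = False,
    add_age_swb: bool = False,
    add_symptom_score: bool = False,
    study_interactions: bool = False,
    per_study: int | None = None,
    standardize_icv: bool = True,
    reference_study: int = 5,
):
    """Build (y, X, names, rows) for one region x hemisphere model."""
    vcol = f"volume_{region}_{hemi}"
    needed = [outcome, vcol, "icv", "sex", "age_mri"]
    if add_age_swb:
        needed.append("age_swb")
    if add_symptom_score:
        needed.append("symptom_class")
    for col in needed:
        if col not in cohort.columns:
            raise ValueError(f"missing covariate column {col!r}")
    df = cohort if per_study is None else cohort[cohort["study"] == per_study]
    sub = df.dropna(subset=needed)
    dropped = len(df) - len(sub)
    if dropped:
        logger.info("listwise deletion removed %d rows for %s_%s",
                    dropped, region, hemi)

    vol = sub[vcol].to_numpy(float)
    v1 = zscore(vol) if standardize else vol
    cols = [np.ones(len(sub)), v1]
    names = ["intercept", "volume_linear"]
    if not drop_quadratic:
        cols.append(v1 ** 2)
        names.append("volume_quadratic")
    icv = sub["icv"].to_numpy(float)
    cols.append(zscore(icv) if standardize_icv else icv)
    names.append("icv")
    cols.append((sub["sex"] == "M").to_numpy(float))
    names.append("sex_m")
    cols.append(sub["age_mri"].to_numpy(float))
    names.append("age_mri")
    if add_age_swb:
        cols.append(sub["age_swb"].to_numpy(float))
        names.append("age_swb")
    if add_symptom_score:
        cols.append(sub["symptom_class"].to_numpy(float))
        names.append("symptom_class")
    if per_study is None:
        studies = sorted(cohort["study"].unique())
        others = [s for s in studies if s != reference_study]
        for s in others:
            cols.append((sub["study"] == s).to_numpy(float))
            names.append(f"study_{s}")
        if study_interactions:
            for s in others:
                dummy = (sub["study"] == s).to_numpy(float)
                cols.append(v1 * dummy)
                names.append(f"volume_linear:study_{s}")
            if not drop_quadratic:
                for s in others:
                    dummy = (sub["study"] == s).to_numpy(float)
                    cols.append(v1 ** 2 * dummy)
                    names.append(f"volume_quadratic:study_{s}")
    y = sub[outcome].to_numpy(float)
    x = np.column_stack(cols)
    return y, x, names, sub.index


class _EigCache:
    """Per-cohort cache of kinship eigendecompositions keyed by row subset."""

    def __init__(self, cohort: pd.DataFrame):
        self.cohort = cohort
        self.k_full = build_kinship(cohort)
        self.pos = {ix: i for i, ix in enumerate(cohort.index)}
        self._cache: dict[tuple, KinshipEigen] = {}

    def get(self, rows) -> KinshipEigen:
        key = tuple(rows)
        if key not in self._cache:
            idx = [self.pos[r] for r in rows]
            self._cache[key] = KinshipEigen(self.k_full[np.ix_(idx, idx)])
        return self._cache[key]


def _fit_region(cohort, cache: _EigCache, region, hemi, **kwargs) -> tuple:
    y, x, names, rows = _design_for_region(cohort, region, hemi, **kwargs)
    eig = cache.get(rows)
    fit = fit_kinship_lmm(y, x, eig=eig, term_names=names)
    return fit, names


def _term_row(fit: LmmFit, term: str) -> dict:
    j = fit.term_index(term)
    f, df, p = test_fixed_term(fit, term)
    return {"est": float(fit.beta[j]), "se": float(fit.se[j]),
            "df": df, "F": f, "p": p}


# these are library operations, not pytest tests
test_fixed_term.__test__ = False
test_joint_terms.__test__ = False


def association_scan(
    cohort: pd.DataFrame,
    regions: list[str] | None = None,
    *,
    outcome: str = "swb",
    standardize: bool = True,
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """Mixed-model scan of the outcome over region x hemisphere volumes.

    One row per region and hemisphere (14 in the full scan), each carrying
    the linear and quadratic volume-term estimates, SEs, Satterthwaite df,
    F and p, with significance flags at the Bonferroni-corrected alpha.
    """
    regions = REGIONS if regions is None else list(regions)
    cache = _EigCache(cohort)
    rows = []
    for region in regions:
        for hemi in ("L", "R"):
            fit, _ = _fit_region(cohort, cache, region, hemi,
                                 outcome=outcome, standardize=standardize)
            lin = _term_row(fit, "volume_linear")
            quad = _term_row(fit, "volume_quadratic")
            rows.append({
                "region": region, "hemisphere": hemi,
                **{f"linear_{k}": v for k, v in lin.items()},
                **{f"quadratic_{k}": v for k, v in quad.items()},
                "linear_significant": lin["p"] < alpha,
                "quadratic_significant": quad["p"] < alpha,
                "alpha": alpha,
            })
    return pd.DataFrame(rows)


def posthoc_battery(cohort: pd.DataFrame, region: str = "hippocampus",
                    variant: str = "drop_quadratic",
                    *, interaction_alpha: float = 0.05 / 4) -> pd.DataFrame:
    """Re-fit the region association model under a post-hoc variant.

    Variants cover alternative outcomes (SAT or HAP alone), dropping the
    quadratic term, unstandardized volumes, adding age at SWB assessment or
    the psychiatric symptom-score covariate, and study-by-volume interaction
    tests (omnibus over the 4 interaction contrasts, reference study 5).
    """
    if variant not in _POSTHOC_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"choose from {_POSTHOC_VARIANTS}")
    cache = _EigCache(cohort)
    kwargs: dict = {}
    if variant == "outcome_sat":
        kwargs["outcome"] = "sat"
    elif variant == "outcome_hap":
        kwargs["outcome"] = "hap"
    elif variant == "drop_quadratic":
        kwargs["drop_quadratic"] = True
    elif variant == "raw_volumes":
        kwargs["standardize"] = False
    elif variant == "add_age_swb":
        kwargs["add_age_swb"] = True
    elif variant == "add_symptom_score":
        kwargs["add_symptom_score"] = True
    elif variant == "study_interactions":
        kwargs["study_interactions"] = True

    rows = []
    for hemi in ("L", "R"):
        fit, names = _fit_region(cohort, cache, region, hemi, **kwargs)
        if variant == "study_interactions":
            for kind in ("linear", "quadratic"):
                terms = [t for t in names
                         if t.startswith(f"volume_{kind}:study_")]
                f, df, p = test_joint_terms(fit, terms)
                row = {"region": region, "hemisphere": hemi,
                       "test": f"{kind}_by_study_omnibus",
                       "df_num": len(terms), "df": df, "F": f, "p": p,
                       "significant": p < interaction_alpha,
                       "alpha": interaction_alpha}
                rows.append(row)
                for t in terms:
                    ft, dft, pt = test_fixed_term(fit, t)
                    j = fit.term_index(t)
                    rows.append({"region": region, "hemisphere": hemi,
                                 "test": f"contrast_{t}", "df_num": 1,
                                 "df": dft, "F": ft, "p": pt,
                                 "est": float(fit.beta[j]),
                                 "se": float(fit.se[j]),
                                 "significant": pt < 0.05, "alpha": 0.05})
        else:
            lin = _term_row(fit, "volume_linear")
            row = {"region": region, "hemisphere": hemi, "variant": variant,
                   **{f"linear_{k}": v for k, v in lin.items()}}
            if "volume_quadratic" in names:
                quad = _term_row(fit, "volume_quadratic")
                row.update({f"quadratic_{k}": v for k, v in quad.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def swb_by_volume_strata(cohort: pd.DataFrame, region: str = "hippocampus",
                         *, outcome: str = "swb") -> pd.DataFrame:
    """Outcome mean/SD within low / medium / high volume strata.

    Strata partition the Z-scored bilateral mean volume with closed outer
    cutoffs: low Z <= -0.5, medium -0.5 < Z < 0.5, high Z >= 0.5.  An empty
    stratum is reported with n = 0 and an undefined-mean flag.
    """
    cols = [f"volume_{region}_L", f"volume_{region}_R", outcome]
    sub = cohort.dropna(subset=cols)
    z = zscore((zscore(sub[cols[0]].to_numpy(float))
                + zscore(sub[cols[1]].to_numpy(float))) / 2.0)
    y = sub[outcome].to_numpy(float)
    masks = {"low": z <= -0.5,
             "medium": (z > -0.5) & (z < 0.5),
             "high": z >= 0.5}
    rows = []
    for name, m in masks.items():
        n = int(m.sum())
        rows.append({
            "stratum": name, "n": n,
            "mean": float(np.mean(y[m])) if n else np.nan,
            "sd": float(np.std(y[m], ddof=1)) if n > 1 else np.nan,
            "undefined": n == 0,
        })
    return pd.DataFrame(rows)


def two_group_anova_from_summary(n1, m1, s1, n2, m2, s2):
    """One-way two-group ANOVA from group summary statistics.

    Between-group sum of squares about the size-weighted grand mean over the
    pooled within-group mean square; df = n1 + n2 - 2.  Returns (F, df, p).
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    gm = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
    df = n1 + n2 - 2
    msw = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    f = float(ssb / msw)
    return f, df, float(stats.f.sf(f, 1, df))
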