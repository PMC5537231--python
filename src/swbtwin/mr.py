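"""Bidirectional Mendelian randomization by two-stage least squares.

A polygenic score serves as the instrument.  Stage 1 regresses the exposure
on the instrument plus covariates in a kinship mixed model; stage 2
regresses the outcome on the fitted (genetically predicted) exposure plus
covariates.  To accommodate nonlinear exposure-outcome relations, the
stage-1 residual ("environmental") variation is cut into three equal-sized
strata (coded 1..3) that enter stage 2 as a main effect and as an
interaction with the fitted exposure.

Second-stage standard errors computed from the fitted exposure understate
uncertainty; the corrected variant rescales them using residuals formed
with the actual exposure at the second-stage coefficients (the standard
2SLS correction), and is the default for interval estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import (KinshipEigen, LmmFit, build_kinship, fit_kinship_lmm,
                  test_fixed_term, test_joint_terms)

__all__ = [
    "TwoSLSResult",
    "instrument_strength",
    "residual_strata",
    "two_sls",
    "bidirectional_mr",
]


@dataclass
class TwoSLSResult:
    """One direction of a 2SLS Mendelian-randomization test."""

    direction: str
    stage1_f: float
    stage1_df: float
    stage1_p: float
    estimate: float
    se_naive: float
    se_corrected: float
    causal_f: float
    causal_df: float
    causal_p: float
    interaction_f: float | None
    interaction_df: float | None
    interaction_p: float | None
    n: int
    weak_instrument: bool

    @property
    def se(self) -> float:
        return self.se_corrected


def _as_matrix(covariates) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return None, []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(float), list(covariates.columns)
    arr = np.asarray(covariates, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"cov{j}" for j in range(arr.shape[1])]


def instrument_strength(exposure, pgs, covariates=None, k=None,
                        *, eig: KinshipEigen | None = None):
    """First-stage F test of the instrument in a kinship mixed model.

    Returns ``(F, df, p)`` for the polygenic-score coefficient in
    ``exposure ~ instrument + covariates`` with the relatedness random
    effect.
    """
    exposure = np.asarray(exposure, float)
    pgs = np.asarray(pgs, float)
    if np.std(pgs) == 0:
        raise ValueError("instrument has zero variance")
    cov, names = _as_matrix(covariates)
    cols = [np.ones(len(exposure)), pgs]
    term_names = ["intercept", "instrument"]
    if cov is not None:
        cols.extend(cov.T)
        term_names.extend(names)
    x = np.column_stack(cols)
    if k is None and eig is None:
        eig = KinshipEigen(np.eye(len(exposure)))
    fit = fit_kinship_lmm(exposure, x, k, eig=eig, term_names=term_names)
    return test_fixed_term(fit, "instrument")


def residual_strata(residuals, k: int = 3) -> np.ndarray:
    """Equal-sized residual strata coded 1..k, contiguous in residual order.

    Stratum sizes differ by at most one; when n is not divisible by k the
    earlier (lower-residual) strata take the extra members.  Ties are broken
    by stable input order, so codes are a deterministic function of the
    residual ranks.
    """
    residuals = np.asarray(residuals, float)
    n = residuals.shape[0]
    if k < 2:
        raise ValueError("need at least 2 strata")
    if n < k:
        raise ValueError(f"cannot cut {n} residuals into {k} strata")
    order = np.argsort(residuals, kind="stable")
    base, extra = divmod(n, k)
    sizes = [base + (1 if j < extra else 0) for j in range(k)]
    codes = np.empty(n, dtype=int)
    start = 0
    for j, size in enumerate(sizes, start=1):
        codes[order[start:start + size]] = j
        start += size
    return codes


def two_sls(outcome, exposure, instrument, covariates=None, k=None,
            *, eig: KinshipEigen | None = None, strata: bool = True,
            n_strata: int = 3, direction: str = "exposure->outcome",
            weak_f_threshold: float = 10.0) -> TwoSLSResult:
    """Two-stage least squares with kinship mixed models at both stages.

    With ``strata`` (default) the stage-1 residual strata enter stage 2 as
    main effects and fitted-exposure interactions; ``strata=False`` gives
    the plain 2SLS estimator (which, with no covariates and K = I, equals
    the textbook instrumental-variables closed form).
    """
    y = np.asarray(outcome, float)
    xexp = np.asarray(exposure, float)
    z = np.asarray(instrument, float)
    n = y.shape[0]
    cov, cov_names = _as_matrix(covariates)
    if eig is None:
        eig = KinshipEigen(np.eye(n) if k is None else k)

    # stage 1
    cols = [np.ones(n), z]
    names = ["intercept", "instrument"]
    if cov is not None:
        cols.extend(cov.T)
        names.extend(cov_names)
    x1 = np.column_stack(cols)
    try:
        fit1 = fit_kinship_lmm(xexp, x1, eig=eig, term_names=names)
    except ValueError as err:
        if "rank deficient" in str(err):
            raise ValueError("instrument is collinear with the covariates"
                             ) from err
        raise
    s1_f, s1_df, s1_p = test_fixed_term(fit1, "instrument")
    fitted = x1 @ fit1.beta
    resid1 = xexp - fitted

    # stage 2
    cols2 = [np.ones(n), fitted]
    names2 = ["intercept", "fitted_exposure"]
    if cov is not None:
        cols2.extend(cov.T)
        names2.extend(cov_names)
    if strata:
        codes = residual_strata(resid1, n_strata)
        for j in range(2, n_strata + 1):
            d = (codes == j).astype(float)
            cols2.append(d)
            names2.append(f"stratum_{j}")
        for j in range(2, n_strata + 1):
            d = (codes == j).astype(float)
            cols2.append(fitted * d)
            names2.append(f"fitted_exposure:stratum_{j}")
    x2 = np.column_stack(cols2)
    fit2 = fit_kinship_lmm(y, x2, eig=eig, term_names=names2)
    c_f, c_df, c_p = test_fixed_term(fit2, "fitted_exposure")
    j = fit2.term_index("fitted_exposure")
    est = float(fit2.beta[j])
    se_naive = float(fit2.se[j])

    # 2SLS correction: residuals with the actual exposure in place of the
    # fitted one, evaluated in the whitened (GLS) metric
    x2_actual = x2.copy()
    x2_actual[:, j] = xexp
    if strata:
        for jj, name in enumerate(names2):
            if name.startswith("fitted_exposure:stratum_"):
                snum = int(name.rsplit("_", 1)[1])
                x2_actual[:, jj] = xexp * (codes == snum)
    h = fit2.h2_ratio
    d = h * eig.lam + (1.0 - h)
    w = 1.0 / d
    yt = eig.rotate(y)
    rt_fitted = yt - eig.rotate(x2) @ fit2.beta
    rt_actual = yt - eig.rotate(x2_actual) @ fit2.beta
    rss_fitted = float(np.sum(rt_fitted ** 2 * w))
    rss_actual = float(np.sum(rt_actual ** 2 * w))
    scale = np.sqrt(rss_actual / rss_fitted) if rss_fitted > 0 else np.nan
    se_corr = se_naive * scale

    if strata:
        inter = [t for t in names2 if t.startswith("fitted_exposure:")]
        i_f, i_df, i_p = test_joint_terms(fit2, inter)
    else:
        i_f = i_df = i_p = None
    return TwoSLSResult(direction=direction,
                        stage1_f=s1_f, stage1_df=s1_df, stage1_p=s1_p,
                        estimate=est, se_naive=se_naive, se_corrected=se_corr,
                        causal_f=c_f, causal_df=c_df, causal_p=c_p,
                        interaction_f=i_f, interaction_df=i_df,
                        interaction_p=i_p, n=n,
                        weak_instrument=s1_f < weak_f_threshold)


def bidirectional_mr(cohort: pd.DataFrame, region: str = "hippocampus",
                     *, dna_only: bool = True,
                     n_pcs: int | None = None) -> pd.DataFrame:
    """2SLS in both causal directions for the left and right volumes.

    Rows: direction x hemisphere (4 cells), each with first-stage and
    causal-term df/F/p plus the residual-stratum interaction test.
    Covariates: sex, age at MRI, study (factor) and the nuisance principal
    components; the analysis subsets to DNA-available persons by default.
    """
    for col in ("pgs_swb", f"pgs_hip_L", f"pgs_hip_R"):
        if col not in cohort.columns:
            raise ValueError(f"missing polygenic-score column {col!r}")
    df = cohort[cohort["dna"]] if dna_only and "dna" in cohort.columns \
        else cohort
    pc_cols = sorted((c for c in df.columns if c.startswith("pc_")),
                     key=lambda c: int(c.split("_")[1]))
    if n_pcs is not None:
        pc_cols = pc_cols[:n_pcs]
    needed = ["swb", f"volume_{region}_L", f"volume_{region}_R",
              "sex", "age_mri", "study"] + pc_cols
    df = df.dropna(subset=[c for c in needed if c in df.columns])

    cov_parts = {"sex_m": (df["sex"] == "M").astype(float),
                 "age_mri": df["age_mri"].astype(float)}
    for s in sorted(df["study"].unique())[1:]:
        cov_parts[f"study_{s}"] = (df["study"] == s).astype(float)
    for c in pc_cols:
        cov_parts[c] = df[c].astype(float)
    cov = pd.DataFrame(cov_parts, index=df.index)

    eig = KinshipEigen(build_kinship(df))
    swb = df["swb"].to_numpy(float)
    rows = []
    for hemi in ("L", "R"):
        vol = df[f"volume_{region}_{hemi}"].to_numpy(float)
        fwd = two_sls(vol, swb, df["pgs_swb"].to_numpy(float), cov, eig=eig,
                      direction=f"swb_on_{region}_{hemi}")
        rev = two_sls(swb, vol, df[f"pgs_hip_{hemi}"].to_numpy(float), cov,
                      eig=eig, direction=f"{region}_{hemi}_on_swb")
        for res in (fwd, rev):
            rows.append({
                "direction": ("swb_on_volume" if res is fwd
                              else "volume_on_swb"),
                "hemisphere": hemi, "n": res.n,
                "stage1_F": res.stage1_f, "stage1_df": res.stage1_df,
                "stage1_p": res.stage1_p,
                "estimate": res.estimate, "se": res.se_corrected,
                "df": res.causal_df, "F": res.causal_f, "p": res.causal_p,
                "interaction_F": res.interaction_f,
                "interaction_df": res.interaction_df,
                "interaction_p": res.interaction_p,
                "weak_instrument": res.weak_instrument,
            })
    return pd.DataFrame(rows)
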