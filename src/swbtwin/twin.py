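"""Multivariate twin covariance-structure modeling.

Fits saturated, ADE, AE and E models to monozygotic (MZ) and dizygotic (DZ)
twin-pair data by maximum likelihood.  The phenotypic covariance of ``p``
traits is decomposed as ``Sigma_Ph = Sigma_A + Sigma_D + Sigma_E`` (additive
genetic, dominance genetic, unshared environment).  The expected ``2p x 2p``
within-pair covariance has cross-twin blocks ``Sigma_A + Sigma_D`` for MZ
pairs and ``0.5*Sigma_A + 0.25*Sigma_D`` for DZ pairs, reflecting the
expected additive and dominance genetic correlations between twins.

Each component matrix is parameterized through its Cholesky factor, which
guarantees positive semi-definiteness.  Means are modeled per trait as a
linear function of covariates (study, age, sex in the pipeline) and are
estimated jointly with the covariance structure by exact coordinate ascent:
a generalized-least-squares mean update given the covariance, alternating
with a quasi-Newton covariance update given the means.  Pairs with a missing
co-twin contribute through the marginal likelihood of their observed entries
(full-information handling).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinData",
    "TwinFit",
    "assemble_twin_pairs",
    "expected_twin_cov",
    "fit_saturated",
    "fit_biometric",
    "likelihood_ratio_test",
    "chi2_sf",
]

_LOG2PI = np.log(2.0 * np.pi)

# model nesting order for likelihood-ratio tests (larger = more general)
_MODEL_ORDER = {"saturated": 3, "ADE": 2, "AE": 1, "E": 0}


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------

@dataclass
class TwinData:
    """Stacked 2p-vectors for MZ and DZ pairs plus per-member covariates."""

    mz: np.ndarray          # (n_mz, 2p), NaN = missing entry
    dz: np.ndarray          # (n_dz, 2p)
    traits: list[str]
    mz_cov: np.ndarray      # (n_mz, 2, c) member covariates, 0-filled if absent
    dz_cov: np.ndarray
    covariate_names: list[str]

    @property
    def p(self) -> int:
        return len(self.traits)


def assemble_twin_pairs(
    cohort: pd.DataFrame,
    traits: list[str],
    covariates: tuple[str, ...] = (),
) -> TwinData:
    """Stack cohort rows into one 2p-vector per twin pair.

    Twins are identified by ``family_id`` plus the ``zygosity_role`` tokens
    MZ1/MZ2 and DZ1/DZ2; extra siblings (role SIB) are excluded from twin
    modeling.  Incomplete pairs are retained with NaN entries for the absent
    co-twin so that full-information fitting can use them.  ``study`` in
    ``covariates`` is expanded to drop-first dummy columns.
    """
    missing = [t for t in traits if t not in cohort.columns]
    if missing:
        raise ValueError(f"traits not in cohort: {missing}")
    p = len(traits)

    cov_cols: list[str] = []
    cov_frame = pd.DataFrame(index=cohort.index)
    for c in covariates:
        if c == "study":
            studies = sorted(cohort["study"].unique())
            for s in studies[1:]:
                name = f"study_{s}"
                cov_frame[name] = (cohort["study"] == s).astype(float)
                cov_cols.append(name)
        elif c == "sex":
            cov_frame["sex_m"] = (cohort["sex"] == "M").astype(float)
            cov_cols.append("sex_m")
        else:
            cov_frame[c] = pd.to_numeric(cohort[c], errors="coerce")
            cov_cols.append(c)

    rows_mz: list[np.ndarray] = []
    rows_dz: list[np.ndarray] = []
    covs_mz: list[np.ndarray] = []
    covs_dz: list[np.ndarray] = []
    c = len(cov_cols)

    for fam, grp in cohort.groupby("family_id", sort=True):
        roles = grp["zygosity_role"].tolist()
        has_mz = any(r.startswith("MZ") for r in roles)
        has_dz = any(r.startswith("DZ") for r in roles)
        if has_mz and has_dz and not any(r == "SIB" for r in roles):
            # a family may hold an MZ pair plus a co-sibling, but twin roles
            # of both zygosities in one family are contradictory
            raise ValueError(f"zygosity conflict in family {fam}")
        for zy in ("MZ", "DZ"):
            members = grp[grp["zygosity_role"].isin([f"{zy}1", f"{zy}2"])]
            if members.empty:
                continue
            if len(members) > 2:
                raise ValueError(f"family {fam} has >2 {zy} twins")
            if has_mz and has_dz and zy == "DZ":
                raise ValueError(f"zygosity conflict in family {fam}")
            vec = np.full(2 * p, np.nan)
            cmat = np.zeros((2, c))
            for _, person in members.iterrows():
                m = 0 if person["zygosity_role"].endswith("1") else 1
                vec[m * p:(m + 1) * p] = [person[t] for t in traits]
                if c:
                    cmat[m] = cov_frame.loc[person.name].to_numpy(float)
            if zy == "MZ":
                rows_mz.append(vec)
                covs_mz.append(cmat)
            else:
                rows_dz.append(vec)
                covs_dz.append(cmat)

    def _stack(rows, covs):
        if rows:
            return np.asarray(rows), np.asarray(covs)
        return np.empty((0, 2 * p)), np.empty((0, 2, c))

    mz, mz_cov = _stack(rows_mz, covs_mz)
    dz, dz_cov = _stack(rows_dz, covs_dz)
    return TwinData(mz=mz, dz=dz, traits=list(traits),
                    mz_cov=mz_cov, dz_cov=dz_cov, covariate_names=cov_cols)


# ---------------------------------------------------------------------------
# expected covariance structure
# ---------------------------------------------------------------------------

def expected_twin_cov(sigma_a: np.ndarray, sigma_d: np.ndarray,
                      sigma_e: np.ndarray, zygosity: str) -> np.ndarray:
    """Expected 2p x 2p twin covariance for a zygosity ('MZ' or 'DZ').

    Diagonal blocks are the phenotypic covariance A + D + E.  Cross-twin
    blocks are A + D for MZ pairs and 0.5*A + 0.25*D for DZ pairs.
    """
    sigma_a = np.atleast_2d(np.asarray(sigma_a, float))
    sigma_d = np.atleast_2d(np.asarray(sigma_d, float))
    sigma_e = np.atleast_2d(np.asarray(sigma_e, float))
    ph = sigma_a + sigma_d + sigma_e
    if zygosity == "MZ":
        cross = sigma_a + sigma_d
    elif zygosity == "DZ":
        cross = 0.5 * sigma_a + 0.25 * sigma_d
    else:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    top = np.hstack([ph, cross])
    bot = np.hstack([cross, ph])
    return np.vstack([top, bot])


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _pattern_groups(y: np.ndarray):
    """Group row indices of y by missingness pattern (tuple of observed idx)."""
    obs = ~np.isnan(y)
    groups: dict[tuple[int, ...], list[int]] = {}
    for i in range(y.shape[0]):
        key = tuple(np.flatnonzero(obs[i]))
        if key:
            groups.setdefault(key, []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


def _loglik_patterns(resid: np.ndarray, sigma: np.ndarray, groups) -> float:
    ll = 0.0
    for oidx, rows in groups.items():
        o = np.asarray(oidx)
        sub = sigma[np.ix_(o, o)]
        try:
            chol = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return -np.inf
        r = resid[rows][:, o]
        w = np.linalg.solve(chol, r.T)
        quad = np.sum(w * w)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        k = len(o)
        ll += -0.5 * (len(rows) * (k * _LOG2PI + logdet) + quad)
    return ll


def _mean_design(data: TwinData):
    """Full (n, 2p, q) design tensors mapping mean parameters to entries.

    Mean parameters are ordered trait-major: for trait t, an intercept then
    one slope per covariate: q = p * (1 + c).
    """
    p, c = data.p, len(data.covariate_names)
    q = p * (1 + c)

    def build(y, cov):
        n = y.shape[0]
        z = np.zeros((n, 2 * p, q))
        for m in range(2):
            feats = np.concatenate([np.ones((n, 1)), cov[:, m, :]], axis=1)
            for t in range(p):
                j = m * p + t
                z[:, j, t * (1 + c):(t + 1) * (1 + c)] = feats
        return z

    return build(data.mz, data.mz_cov), build(data.dz, data.dz_cov), q


def _gls_mean_step(data: TwinData, z_mz, z_dz, sig_mz, sig_dz, q):
    """Exact GLS update of mean parameters given the two covariances."""
    a = np.zeros((q, q))
    b = np.zeros(q)
    for y, z, sigma in ((data.mz, z_mz, sig_mz), (data.dz, z_dz, sig_dz)):
        if y.shape[0] == 0:
            continue
        for oidx, rows in _pattern_groups(y).items():
            o = np.asarray(oidx)
            w = np.linalg.inv(sigma[np.ix_(o, o)])
            zo = z[rows][:, o, :]
            yo = y[rows][:, o]
            a += np.einsum("ioq,or,irs->qs", zo, w, zo)
            b += np.einsum("ioq,or,ir->q", zo, w, yo)
    return np.linalg.solve(a, b)


def _residuals(y, z, beta):
    return y - z @ beta


# --- component parameterization --------------------------------------------

def _tril_indices(p):
    return np.tril_indices(p)


def _chol_to_vec(l: np.ndarray) -> np.ndarray:
    return l[_tril_indices(l.shape[0])]


def _vec_to_chol(v: np.ndarray, p: int) -> np.ndarray:
    l = np.zeros((p, p))
    l[_tril_indices(p)] = v
    return l


def _psd_project(m: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    floor = max(eps, eps * max(w.max(), 1.0))
    w = np.clip(w, floor, None)
    return (v * w) @ v.T


@dataclass
class _CovParam:
    """Cholesky parameterization of the included variance components."""

    model: str                  # 'ADE' | 'AE' | 'E' | 'saturated'
    p: int
    zero_a_first_col: bool = False   # fix Sigma_A cross terms with trait 0 to 0
    zero_e_first_col: bool = False

    def components(self) -> list[str]:
        if self.model == "ADE":
            return ["A", "D", "E"]
        if self.model == "AE":
            return ["A", "E"]
        if self.model == "E":
            return ["E"]
        raise ValueError(self.model)

    def free_mask(self, comp: str) -> np.ndarray:
        """Boolean mask over lower-tri entries that are free parameters."""
        p = self.p
        rows, cols = _tril_indices(p)
        mask = np.ones(rows.size, dtype=bool)
        zero = (comp == "A" and self.zero_a_first_col) or \
               (comp == "E" and self.zero_e_first_col)
        if zero:
            mask &= ~((cols == 0) & (rows > 0))
        return mask

    def n_free(self) -> int:
        return sum(int(self.free_mask(c).sum()) for c in self.components())

    def pack(self, mats: dict[str, np.ndarray]) -> np.ndarray:
        out = []
        for comp in self.components():
            l = np.linalg.cholesky(_psd_project(mats[comp]))
            out.append(_chol_to_vec(l)[self.free_mask(comp)])
        return np.concatenate(out)

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        p = self.p
        mats = {}
        pos = 0
        for comp in self.components():
            mask = self.free_mask(comp)
            v = np.zeros(mask.size)
            k = int(mask.sum())
            v[mask] = theta[pos:pos + k]
            pos += k
            l = _vec_to_chol(v, p)
            mats[comp] = l @ l.T
        for comp in ("A", "D", "E"):
            mats.setdefault(comp, np.zeros((p, p)))
        return mats


def _cov_nll_factory(data: TwinData, param: _CovParam, resid_mz, resid_dz,
                     groups_mz, groups_dz):
    def nll(theta):
        mats = param.unpack(theta)
        sig_mz = expected_twin_cov(mats["A"], mats["D"], mats["E"], "MZ")
        sig_dz = expected_twin_cov(mats["A"], mats["D"], mats["E"], "DZ")
        # small ridge keeps the MZ covariance invertible when D/E degenerate
        jitter = 1e-10 * (np.trace(sig_mz) / sig_mz.shape[0] + 1.0)
        sig_mz = sig_mz + jitter * np.eye(sig_mz.shape[0])
        sig_dz = sig_dz + jitter * np.eye(sig_dz.shape[0])
        ll = _loglik_patterns(resid_mz, sig_mz, groups_mz)
        ll += _loglik_patterns(resid_dz, sig_dz, groups_dz)
        if not np.isfinite(ll):
            return 1e12
        return -ll
    return nll


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class TwinFit:
    """Maximum-likelihood twin-model fit."""

    model: str
    traits: list[str]
    sigma_a: np.ndarray
    sigma_d: np.ndarray
    sigma_e: np.ndarray
    means: np.ndarray
    loglik: float
    n_parameters: int
    n_mz: int
    n_dz: int
    constraints: frozenset = field(default_factory=frozenset)
    converged: bool = True

    @property
    def sigma_ph(self) -> np.ndarray:
        return self.sigma_a + self.sigma_d + self.sigma_e

    @property
    def h2(self) -> np.ndarray:
        return np.diag(self.sigma_a) / np.diag(self.sigma_ph)

    @property
    def d2(self) -> np.ndarray:
        return np.diag(self.sigma_d) / np.diag(self.sigma_ph)

    def _corr(self, m: np.ndarray) -> np.ndarray:
        d = np.sqrt(np.clip(np.diag(m), 1e-300, None))
        return m / np.outer(d, d)

    @property
    def rg(self) -> np.ndarray:
        return self._corr(self.sigma_a)

    @property
    def re(self) -> np.ndarray:
        return self._corr(self.sigma_e)

    def implied_twin_correlations(self) -> pd.DataFrame:
        """Per-trait cross-twin correlations implied by the components."""
        ph = np.diag(self.sigma_ph)
        mz = (np.diag(self.sigma_a) + np.diag(self.sigma_d)) / ph
        dz = (0.5 * np.diag(self.sigma_a) + 0.25 * np.diag(self.sigma_d)) / ph
        return pd.DataFrame({"trait": self.traits, "r_mz": mz, "r_dz": dz,
                             "h2": self.h2})


@dataclass
class SaturatedFit:
    """Unconstrained per-zygosity covariance fit (baseline model)."""

    traits: list[str]
    sigma_mz: np.ndarray
    sigma_dz: np.ndarray
    means: np.ndarray
    loglik: float
    n_parameters: int
    n_mz: int
    n_dz: int
    model: str = "saturated"
    constraints: frozenset = field(default_factory=frozenset)

    def twin_correlations(self) -> pd.DataFrame:
        p = len(self.traits)

        def r(sig):
            out = np.empty(p)
            for t in range(p):
                out[t] = sig[t, t + p] / np.sqrt(sig[t, t] * sig[t + p, t + p])
            return out

        return pd.DataFrame({"trait": self.traits,
                             "r_mz": r(self.sigma_mz),
                             "r_dz": r(self.sigma_dz)})


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _complete(y, cov):
    ok = ~np.isnan(y).any(axis=1)
    return y[ok], cov[ok]


def _symmetrize_pair_cov(sig: np.ndarray, p: int) -> np.ndarray:
    """Average over twin-order exchange so co-twin labeling is arbitrary."""
    perm = np.concatenate([np.arange(p, 2 * p), np.arange(p)])
    return 0.5 * (sig + sig[np.ix_(perm, perm)])


def fit_saturated(data: TwinData, *, symmetrize: bool = True,
                  tol: float = 1e-10, max_iter: int = 2000) -> SaturatedFit:
    """ML fit of unconstrained MZ and DZ covariances with a shared mean model.

    Uses complete pairs only.  Alternates the exact GLS mean update with the
    exact per-zygosity scatter update, which converges to the joint maximum
    likelihood.  With ``symmetrize`` the covariance is averaged over twin
    order, reflecting the arbitrary labeling of co-twins.
    """
    p = data.p
    mz, mz_cov = _complete(data.mz, data.mz_cov)
    dz, dz_cov = _complete(data.dz, data.dz_cov)
    if mz.shape[0] < p + 1 or dz.shape[0] < p + 1:
        raise ValueError("need at least p+1 complete pairs per zygosity")
    cdata = TwinData(mz, dz, data.traits, mz_cov, dz_cov, data.covariate_names)
    z_mz, z_dz, q = _mean_design(cdata)

    sig_mz = np.cov(mz, rowvar=False, bias=True) + 1e-8 * np.eye(2 * p)
    sig_dz = np.cov(dz, rowvar=False, bias=True) + 1e-8 * np.eye(2 * p)
    groups_mz = _pattern_groups(mz)
    groups_dz = _pattern_groups(dz)

    last = -np.inf
    beta = np.zeros(q)
    for _ in range(max_iter):
        beta = _gls_mean_step(cdata, z_mz, z_dz, sig_mz, sig_dz, q)
        r_mz = _residuals(mz, z_mz, beta)
        r_dz = _residuals(dz, z_dz, beta)
        new_mz = r_mz.T @ r_mz / mz.shape[0]
        new_dz = r_dz.T @ r_dz / dz.shape[0]
        if symmetrize:
            new_mz = _symmetrize_pair_cov(new_mz, p)
            new_dz = _symmetrize_pair_cov(new_dz, p)
        delta = max(np.abs(new_mz - sig_mz).max(),
                    np.abs(new_dz - sig_dz).max())
        sig_mz, sig_dz = new_mz, new_dz
        ll = (_loglik_patterns(r_mz, sig_mz, groups_mz)
              + _loglik_patterns(r_dz, sig_dz, groups_dz))
        if not np.isfinite(ll):
            raise ValueError("singular saturated covariance estimate; "
                             "more complete pairs are needed")
        if abs(ll - last) < tol and delta < 1e-9:
            last = ll
            break
        last = ll

    # free covariance parameters: two symmetric 2p x 2p matrices; under
    # twin-order symmetry each has p(p+1) free entries instead of p(2p+1)
    n_cov = 2 * (p * (p + 1) if symmetrize else p * (2 * p + 1))
    return SaturatedFit(traits=data.traits, sigma_mz=sig_mz, sigma_dz=sig_dz,
                        means=beta, loglik=last, n_parameters=q + n_cov,
                        n_mz=mz.shape[0], n_dz=dz.shape[0])


def fit_biometric(
    data: TwinData,
    model: str = "AE",
    *,
    zero_swb_cross: str | None = None,
    tol: float = 1e-8,
    n_restarts: int = 5,
    restart_seed: int = 20170731,
    max_outer: int = 200,
) -> TwinFit:
    """ML fit of an ADE / AE / E biometric model.

    ``zero_swb_cross='A'`` constrains the genetic covariances between the
    first trait and all others to zero (likewise ``'E'`` for environmental),
    which is how the omnibus cross-trait correlation tests are formed.
    Incomplete pairs contribute through their observed entries.
    """
    if model not in ("ADE", "AE", "E"):
        raise ValueError(f"unknown model {model!r}")
    p = data.p
    n_mz, n_dz = data.mz.shape[0], data.dz.shape[0]
    if model == "ADE" and (n_dz == 0 or n_mz == 0):
        raise ValueError("ADE model is unidentified without both MZ and DZ "
                         "pairs")
    if model in ("ADE", "AE") and n_mz == 0:
        raise ValueError(f"{model} model needs MZ pairs")

    param = _CovParam(model=model, p=p,
                      zero_a_first_col=(zero_swb_cross == "A"),
                      zero_e_first_col=(zero_swb_cross == "E"))

    z_mz, z_dz, q = _mean_design(data)
    groups_mz = _pattern_groups(data.mz)
    groups_dz = _pattern_groups(data.dz)

    # moment-based starting values from complete pairs
    def _cross_block(y):
        yc = y[~np.isnan(y).any(axis=1)]
        if yc.shape[0] < p + 2:
            return None
        s = np.cov(yc, rowvar=False, bias=True)
        return (_symmetrize_pair_cov(s, p)[:p, p:2 * p],
                _symmetrize_pair_cov(s, p)[:p, :p])

    mzb = _cross_block(data.mz)
    dzb = _cross_block(data.dz)
    sph = mzb[1] if mzb is not None else (dzb[1] if dzb is not None
                                          else np.eye(p))
    c_mz = mzb[0] if mzb is not None else 0.5 * sph
    c_dz = dzb[0] if dzb is not None else 0.25 * sph
    if model == "ADE":
        a0 = 4.0 * c_dz - c_mz
        d0 = 2.0 * c_mz - 4.0 * c_dz
        e0 = sph - a0 - d0
        init = {"A": a0, "D": d0, "E": e0}
    elif model == "AE":
        init = {"A": c_mz, "E": sph - c_mz}
    else:
        init = {"E": sph}
    theta0 = param.pack(init)

    rng = np.random.default_rng(restart_seed)
    best = None
    nll_at = None
    beta = np.zeros(q)
    for attempt in range(max(1, n_restarts)):
        th = theta0 if attempt == 0 else theta0 * (
            1.0 + 0.3 * rng.standard_normal(theta0.shape))
        # coordinate ascent: GLS means <-> covariance quasi-Newton
        last = -np.inf
        ok = False
        for _ in range(max_outer):
            mats = param.unpack(th)
            sig_mz = expected_twin_cov(mats["A"], mats["D"], mats["E"], "MZ")
            sig_dz = expected_twin_cov(mats["A"], mats["D"], mats["E"], "DZ")
            jit = 1e-10 * (np.trace(sig_mz) / (2 * p) + 1.0) * np.eye(2 * p)
            try:
                beta = _gls_mean_step(data, z_mz, z_dz, sig_mz + jit,
                                      sig_dz + jit, q)
            except np.linalg.LinAlgError:
                break
            r_mz = _residuals(data.mz, z_mz, beta)
            r_dz = _residuals(data.dz, z_dz, beta)
            nll_at = _cov_nll_factory(data, param, r_mz, r_dz,
                                      groups_mz, groups_dz)
            res = optimize.minimize(nll_at, th, method="L-BFGS-B",
                                    options={"maxiter": 500, "ftol": 1e-12})
            th = res.x
            ll = -res.fun
            if np.isfinite(ll) and abs(ll - last) < tol:
                ok = True
                last = ll
                break
            last = ll
        if np.isfinite(last) and (best is None or last > best[0]):
            best = (last, th.copy(), beta.copy(), ok)
        if best is not None and best[3]:
            break

    if best is None:
        raise RuntimeError(f"{model} twin model failed to converge after "
                           f"{n_restarts} restarts")
    ll, th, beta, ok = best
    mats = param.unpack(th)
    constraints = frozenset(
        c for c, on in (("rg_swb_vol=0", param.zero_a_first_col),
                        ("re_swb_vol=0", param.zero_e_first_col)) if on)
    return TwinFit(model=model, traits=data.traits,
                   sigma_a=mats["A"], sigma_d=mats["D"], sigma_e=mats["E"],
                   means=beta, loglik=ll, n_parameters=q + param.n_free(),
                   n_mz=n_mz, n_dz=n_dz, constraints=constraints,
                   converged=ok)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def likelihood_ratio_test(full, nested) -> tuple[float, int, float]:
    """Chi-square difference test of a nested model against a fuller one.

    Returns ``(chi2, df, p)`` with ``chi2 = 2 * (loglik_full - loglik_nested)``
    and ``df`` the difference in free parameter counts.  Note that tests of
    variance components on the boundary of the parameter space have
    non-standard null distributions; the naive chi-square p-value is reported
    regardless, with this caveat documented.
    """
    if _MODEL_ORDER.get(full.model) is None or \
            _MODEL_ORDER.get(nested.model) is None:
        raise ValueError("unknown model labels")
    if _MODEL_ORDER[full.model] < _MODEL_ORDER[nested.model]:
        raise ValueError(f"{nested.model} is not nested in {full.model}")
    if full.model == nested.model and \
            not (set(full.constraints) < set(nested.constraints)) and \
            full.n_parameters == nested.n_parameters:
        # identical models: chi2 = 0 by construction
        if full.constraints != nested.constraints:
            raise ValueError("models are not nested")
    df = full.n_parameters - nested.n_parameters
    if df < 0:
        raise ValueError("nested model has more parameters than the full one")
    chi2 = max(0.0, 2.0 * (full.loglik - nested.loglik))
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, chi2_sf(chi2, df)


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return float(stats.chi2.sf(x, df))
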