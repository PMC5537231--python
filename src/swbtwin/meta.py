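"""Per-study association fits pooled by fixed-effect inverse-variance WLS.

Each study's linear and quadratic volume coefficients are estimated in a
within-study kinship mixed model (no study factor) and pooled with weights
``w_i = 1 / SE_i^2``: pooled estimate ``sum(w b) / sum(w)`` and pooled SE
``(sum w)^(-1/2)``.  The pooled p-value is primarily computed from a
two-tailed normal reference on z = estimate/SE; a t reference with k-1
degrees of freedom is reported as a secondary column because the reference
distribution used for printed pooled p-values of this design is ambiguous.
Only a fixed-effect (homogeneity) model is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import _design_for_region, KinshipEigen, build_kinship, \
    fit_kinship_lmm, test_fixed_term

__all__ = ["MetaResult", "pool_fixed", "per_study_fits", "meta_table"]


@dataclass
class MetaResult:
    """Fixed-effect pooled estimate."""

    estimate: float
    se: float
    z: float
    p_normal: float
    p_t: float
    k: int


def pool_fixed(estimates, ses) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study estimates."""
    est = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if est.shape != se.shape or est.ndim != 1 or est.size < 1:
        raise ValueError("estimates and SEs must be equal-length vectors "
                         "with at least one study")
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p_norm = float(2.0 * stats.norm.sf(abs(z)))
    k = est.size
    p_t = float(2.0 * stats.t.sf(abs(z), max(k - 1, 1)))
    return MetaResult(estimate=pooled, se=pooled_se, z=float(z),
                      p_normal=p_norm, p_t=p_t, k=k)


def per_study_fits(cohort: pd.DataFrame, region: str = "hippocampus",
                   *, outcome: str = "swb") -> pd.DataFrame:
    """Within-study association fits (no study factor).

    One row per study x hemisphere x term (linear, quadratic) with the
    estimate, SE, Satterthwaite df, F and p from the kinship mixed model.
    """
    rows = []
    for study in sorted(cohort["study"].unique()):
        sub = cohort[cohort["study"] == study]
        try:
            eig = KinshipEigen(build_kinship(sub))
        except ValueError as err:
            raise ValueError(f"study {study}: {err}") from err
        for hemi in ("L", "R"):
            try:
                y, x, names, rws = _design_for_region(
                    sub, region, hemi, outcome=outcome, per_study=study)
                fit = fit_kinship_lmm(
                    y, x, eig=eig if len(rws) == len(sub) else
                    KinshipEigen(build_kinship(sub.loc[rws])),
                    term_names=names)
            except ValueError as err:
                raise ValueError(f"study {study} ({region} {hemi}): {err}"
                                 ) from err
            for term, label in (("volume_linear", "linear"),
                                ("volume_quadratic", "quadratic")):
                f, dfree, p = test_fixed_term(fit, term)
                j = fit.term_index(term)
                rows.append({"study": study, "hemisphere": hemi,
                             "term": label, "estimate": float(fit.beta[j]),
                             "se": float(fit.se[j]), "df": dfree,
                             "F": f, "p": p})
    return pd.DataFrame(rows)


def meta_table(cohort: pd.DataFrame, region: str = "hippocampus",
               *, outcome: str = "swb",
               alpha: float = 0.05 / 4) -> pd.DataFrame:
    """Per-study rows plus a pooled WLS row per hemisphere x term."""
    per = per_study_fits(cohort, region, outcome=outcome)
    out = [per]
    pooled_rows = []
    for (hemi, term), grp in per.groupby(["hemisphere", "term"], sort=True):
        res = pool_fixed(grp["estimate"].to_numpy(), grp["se"].to_numpy())
        pooled_rows.append({"study": "pooled", "hemisphere": hemi,
                            "term": term, "estimate": res.estimate,
                            "se": res.se, "df": float(res.k - 1),
                            "F": res.z ** 2, "p": res.p_normal,
                            "p_t": res.p_t,
                            "significant": res.p_normal < alpha})
    out.append(pd.DataFrame(pooled_rows))
    return pd.concat(out, ignore_index=True)
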