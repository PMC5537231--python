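"""Minimal univariate and bivariate LD-score regression.

Estimates SNP-heritability from the regression of squared GWAS Z-scores on
per-SNP LD scores, ``E[z_j^2] = (N h2 / M) l_j + intercept``, and the
genetic covariance of two traits from the cross-product regression,
``E[z1_j z2_j] = (sqrt(N1 N2) rho_g / M) l_j + intercept``.  The genetic
correlation is ``rg = rho_g / sqrt(h2_1 h2_2)``.  Standard errors come from
a delete-a-block jackknife over contiguous SNP blocks (the whole
three-regression pipeline is recomputed per deleted block for rg).

Weights default to the heteroskedasticity weighting
``1 / (l_j * (expected statistic)^2)`` with a single reweighting pass from
an initial unweighted fit; an unweighted fallback is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SummaryStatsPair

__all__ = [
    "LdscResult",
    "h2_regression",
    "rg_regression",
    "z_two_tailed",
    "read_sumstats_pair",
]

DEFAULT_BLOCKS = 200
_MIN_SNPS_PER_BLOCK = 10


@dataclass
class LdscResult:
    """Bivariate LD-score regression estimates."""

    h2_1: float
    h2_2: float
    gencov: float
    rg: float
    rg_se: float
    z: float
    p: float
    intercept_1: float
    intercept_2: float
    intercept_cross: float
    n_blocks: int
    defined: bool = True


def _resolve_blocks(m: int, n_blocks: int) -> int:
    n_blocks = min(n_blocks, m // _MIN_SNPS_PER_BLOCK)
    if n_blocks < 2:
        raise ValueError(f"too few SNPs ({m}) for jackknife blocks")
    return n_blocks


def _wls(y: np.ndarray, ell: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on [1, ell]; returns (slope, intercept)."""
    sw = np.sqrt(w)
    x = np.column_stack([np.ones_like(ell), ell]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(x, y * sw, rcond=None)
    return float(coef[1]), float(coef[0])


def _weights(ell, expected, weighted):
    if not weighted:
        return np.ones_like(ell)
    return 1.0 / (np.maximum(ell, 1.0) * np.maximum(expected, 0.1) ** 2)


def _h2_point(z, ell, n, m, weighted):
    y = z ** 2
    slope0, int0 = _wls(y, ell, np.ones_like(ell))
    expected = np.maximum(int0 + slope0 * ell, 1e-2)
    w = _weights(ell, expected, weighted)
    slope, intercept = _wls(y, ell, w)
    return slope * m / n, intercept


def _gencov_point(z1, z2, ell, n1, n2, m, exp1, exp2, weighted):
    y = z1 * z2
    slope0, int0 = _wls(y, ell, np.ones_like(ell))
    cross = int0 + slope0 * ell
    expected = exp1 * exp2 + cross ** 2
    w = _weights(ell, expected, weighted)
    slope, intercept = _wls(y, ell, w)
    return slope * m / np.sqrt(n1 * n2), intercept


def _jackknife(values: np.ndarray):
    b = values.shape[0]
    mean = values.mean()
    se = float(np.sqrt((b - 1) / b * np.sum((values - mean) ** 2)))
    return se


def h2_regression(z, ell, n, m=None, *, n_blocks: int = DEFAULT_BLOCKS,
                  weighted: bool = True):
    """SNP-heritability from LD-score regression of z^2 on l.

    Returns ``(h2, intercept, jackknife SE of h2)``; ``m`` defaults to the
    number of SNPs supplied.
    """
    z = np.asarray(z, float)
    ell = np.asarray(ell, float)
    if z.shape != ell.shape:
        raise ValueError("z and LD scores differ in length")
    if not np.all(np.isfinite(z)) or not np.all(np.isfinite(ell)):
        raise ValueError("non-finite values in the input")
    if np.any(ell < 1.0 - 1e-9):
        raise ValueError("LD scores must be >= 1")
    m_snps = z.shape[0]
    m = m_snps if m is None else int(m)
    n_blocks = _resolve_blocks(m_snps, n_blocks)
    h2, intercept = _h2_point(z, ell, n, m, weighted)
    bounds = np.linspace(0, m_snps, n_blocks + 1).astype(int)
    reps = np.empty(n_blocks)
    for b in range(n_blocks):
        keep = np.ones(m_snps, dtype=bool)
        keep[bounds[b]:bounds[b + 1]] = False
        reps[b], _ = _h2_point(z[keep], ell[keep], n, m, weighted)
    return h2, intercept, _jackknife(reps)


def rg_regression(pair: SummaryStatsPair, *, n_blocks: int = DEFAULT_BLOCKS,
                  weighted: bool = True) -> LdscResult:
    """Genetic correlation by bivariate LD-score regression with jackknife SE.

    A non-positive heritability estimate for either trait leaves rg
    undefined; the result is returned with ``defined=False``.
    """
    t = pair.table
    z1 = t["z1"].to_numpy(float)
    z2 = t["z2"].to_numpy(float)
    ell = t["ld_score"].to_numpy(float)
    m_snps = z1.shape[0]
    n_blocks = _resolve_blocks(m_snps, n_blocks)

    def full(z1s, z2s, ells):
        h1, i1 = _h2_point(z1s, ells, pair.n1, pair.m, weighted)
        h2, i2 = _h2_point(z2s, ells, pair.n2, pair.m, weighted)
        exp1 = np.maximum(i1 + pair.n1 * h1 * ells / pair.m, 1e-2)
        exp2 = np.maximum(i2 + pair.n2 * h2 * ells / pair.m, 1e-2)
        gencov, ic = _gencov_point(z1s, z2s, ells, pair.n1, pair.n2, pair.m,
                                   exp1, exp2, weighted)
        if h1 <= 0 or h2 <= 0:
            return h1, h2, gencov, np.nan, i1, i2, ic
        return h1, h2, gencov, gencov / np.sqrt(h1 * h2), i1, i2, ic

    h1, h2, gencov, rg, i1, i2, ic = full(z1, z2, ell)
    if not np.isfinite(rg):
        return LdscResult(h2_1=h1, h2_2=h2, gencov=gencov, rg=np.nan,
                          rg_se=np.nan, z=np.nan, p=np.nan, intercept_1=i1,
                          intercept_2=i2, intercept_cross=ic,
                          n_blocks=n_blocks, defined=False)

    bounds = np.linspace(0, m_snps, n_blocks + 1).astype(int)
    reps = np.empty(n_blocks)
    for b in range(n_blocks):
        keep = np.ones(m_snps, dtype=bool)
        keep[bounds[b]:bounds[b + 1]] = False
        rep = full(z1[keep], z2[keep], ell[keep])[3]
        reps[b] = rep if np.isfinite(rep) else rg
    se = _jackknife(reps)
    z = rg / se if se > 0 else np.nan
    return LdscResult(h2_1=h1, h2_2=h2, gencov=gencov, rg=rg, rg_se=se,
                      z=float(z), p=z_two_tailed(z), intercept_1=i1,
                      intercept_2=i2, intercept_cross=ic, n_blocks=n_blocks)


def z_two_tailed(z: float) -> float:
    """Two-tailed normal p-value: 2 * (1 - Phi(|z|))."""
    if not np.isfinite(z):
        return np.nan
    return float(2.0 * stats.norm.sf(abs(z)))


def read_sumstats_pair(path1, path2, ld_path) -> SummaryStatsPair:
    """Assemble a SummaryStatsPair from two sumstats TSVs and an LD-score TSV.

    Files follow the conventional layout: SNP/Z/N for each trait and SNP/L2
    for the LD scores; SNPs are matched by identifier.
    """
    s1 = pd.read_csv(path1, sep="\t")
    s2 = pd.read_csv(path2, sep="\t")
    ld = pd.read_csv(ld_path, sep="\t")
    for frame, cols, name in ((s1, {"SNP", "Z", "N"}, path1),
                              (s2, {"SNP", "Z", "N"}, path2),
                              (ld, {"SNP", "L2"}, ld_path)):
        if not cols.issubset(frame.columns):
            raise ValueError(f"{name}: expected columns {sorted(cols)}")
    merged = s1.merge(s2, on="SNP", suffixes=("_1", "_2")).merge(ld, on="SNP")
    table = pd.DataFrame({"snp": merged["SNP"], "ld_score": merged["L2"],
                          "z1": merged["Z_1"], "z2": merged["Z_2"]})
    return SummaryStatsPair(table=table, n1=int(merged["N_1"].iloc[0]),
                            n2=int(merged["N_2"].iloc[0]), m=len(merged),
                            true_h2_1=np.nan, true_h2_2=np.nan,
                            true_rg=np.nan)
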