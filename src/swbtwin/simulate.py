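"""Synthetic twin-family cohorts and GWAS summary statistics.

Emulates the structure of a five-study twin-register MRI sample: MZ/DZ twin
pairs with extra siblings, a subjective well-being (SWB) composite built
from satisfaction-with-life (SAT, 5-35) and subjective-happiness (HAP,
4-28) scales, intracranial volume and 14 subcortical volumes (7 regions x
2 hemispheres), polygenic scores usable as Mendelian-randomization
instruments, nuisance principal-component covariates, and symptom-based
selection in the first three studies.

The generative model plants, by default:
  * additive-genetic latents shared with correlation 1.0 within MZ pairs
    and 0.5 within DZ pairs and sibling dyads (via a family component),
  * heritabilities of 0.44 for SWB and 0.76 for volumes,
  * a concave link from hippocampal volume to SWB (linear 0.74, quadratic
    -0.33 SWB units per volume SD),
  * weak genetic (0.07) and modest environmental (0.18) SWB-hippocampus
    correlations, and left/right genetic (0.95) and environmental (0.30)
    within-region correlations.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .twin import TwinData, expected_twin_cov

__all__ = [
    "SimulationParams",
    "SelectionRule",
    "SummaryStatsPair",
    "REGIONS",
    "COHORT_COLUMNS",
    "simulate_cohort",
    "apply_symptom_selection",
    "simulate_gwas_pair",
    "simulate_twin_pairs",
    "swb_composite",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_sumstats",
]

REGIONS = ["caudate", "putamen", "pallidum", "thalamus", "hippocampus",
           "amygdala", "accumbens"]

# mm^3; typical FreeSurfer-scale subcortical volumes
_VOL_MEANS = {"caudate": 3700.0, "putamen": 5100.0, "pallidum": 1800.0,
              "thalamus": 7600.0, "hippocampus": 4200.0, "amygdala": 1650.0,
              "accumbens": 620.0}
_VOL_SDS = {r: 0.1 * m for r, m in _VOL_MEANS.items()}

# per-study family composition of the five-study sample:
# (MZ pairs, DZ pairs, single MZ, single DZ, siblings, MZ+co-sib triplets)
_PAPER_LAYOUT = {
    1: (26, 1, 3, 1, 0, 0),
    2: (69, 45, 6, 4, 6, 0),
    3: (24, 2, 6, 0, 0, 0),
    4: (15, 30, 8, 11, 21, 0),
    5: (36, 45, 0, 9, 60, 1),
}
_PAPER_SEX = {1: (20, 38), 2: (92, 152), 3: (22, 36), 4: (64, 66),
              5: (104, 130)}
# age at MRI: (mean, sd, low, high); SWB assessment delay in years
_PAPER_AGE_MRI = {1: (14.7, 1.5, 11.0, 18.0), 2: (34.0, 10.2, 19.0, 57.0),
                  3: (30.0, 5.9, 20.0, 42.0), 4: (28.7, 6.5, 19.1, 55.9),
                  5: (10.0, 1.3, 9.0, 15.0)}
_PAPER_SWB_DELAY = {1: 3.4, 2: -2.7, 3: 2.6, 4: 8.9, 5: 7.2}


@dataclass(frozen=True)
class SelectionRule:
    """Symptom-based selection for one study: counts or quantile cuts."""

    n_high: int | None = None
    n_low: int | None = None
    q_high: float | None = None
    q_low: float | None = None


@dataclass
class SimulationParams:
    """Generating parameters for the synthetic cohort.

    The defaults reproduce the five-study design: exact per-study family
    composition and sex split, study-specific age distributions, and the
    planted effect sizes listed in the module docstring.
    """

    layout: str = "paper"                       # 'paper' | 'random'
    n_families_per_study: tuple = (31, 124, 32, 64, 91)
    sib_count_distribution: tuple = (0.7, 0.2, 0.1)
    mz_fraction: float = 0.55
    triplets: bool = False                      # random layout only
    h2_targets: dict = field(default_factory=lambda: {
        "swb": 0.44, "volume": 0.76, "icv": 0.80})
    d2_targets: dict = field(default_factory=dict)
    rg_swb_vol: float = 0.07
    re_swb_vol: float = 0.18
    lin_beta: float = 0.74
    quad_beta: float = -0.33
    swb_mean: float = 24.9
    swb_sd: float = 4.1
    sat_hap_split_sd: float = 2.3
    vol_means: dict = field(default_factory=lambda: dict(_VOL_MEANS))
    vol_sds: dict = field(default_factory=lambda: dict(_VOL_SDS))
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    icv_volume_fraction: float = 0.15
    age_ranges_per_study: dict = field(
        default_factory=lambda: dict(_PAPER_AGE_MRI))
    swb_delay_per_study: dict = field(
        default_factory=lambda: dict(_PAPER_SWB_DELAY))
    pgs_r2_exposure: dict = field(default_factory=lambda: {
        "swb": 0.015, "hip": 0.025})
    selection_spec: dict = field(default_factory=lambda: {
        1: SelectionRule(n_high=23, n_low=35),
        2: SelectionRule(n_high=75, n_low=167),
        3: SelectionRule(n_high=23, n_low=35)})
    symptom_swb_corr: float = -0.8
    sex_effect_swb: float = 0.0
    sex_effect_vol: float = 0.0
    n_pc_covariates: int = 11
    dna_n: int = 636
    seed: int = 0

    # latent correlation structure of the volumes
    genetic_common: float = 0.40     # cross-region genetic correlation
    genetic_lr_extra: float = 0.55   # extra shared by L/R of one region
    env_lr: float = 0.30             # L/R environmental correlation

    def validate(self) -> None:
        for trait, h2 in self.h2_targets.items():
            d2 = self.d2_targets.get(trait, 0.0)
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"h2_targets[{trait!r}] outside [0, 1]")
            if not 0.0 <= d2 <= 1.0:
                raise ValueError(f"d2_targets[{trait!r}] outside [0, 1]")
            if h2 + d2 > 1.0:
                raise ValueError(f"h2+d2 > 1 for trait {trait!r}")
        for name in ("rg_swb_vol", "re_swb_vol", "symptom_swb_corr"):
            if abs(getattr(self, name)) > 1.0:
                raise ValueError(f"{name} outside [-1, 1]")
        if not 0.0 <= self.mz_fraction <= 1.0:
            raise ValueError("mz_fraction outside [0, 1]")
        if abs(sum(self.sib_count_distribution) - 1.0) > 1e-9 or \
                min(self.sib_count_distribution) < 0:
            raise ValueError("sib_count_distribution is not a probability "
                             "vector")
        for name in ("genetic_common", "genetic_lr_extra", "env_lr",
                     "icv_volume_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.genetic_common + self.genetic_lr_extra > 1.0:
            raise ValueError("genetic_common + genetic_lr_extra > 1 gives a "
                             "non-PSD generating covariance")
        for t, r2 in self.pgs_r2_exposure.items():
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"pgs_r2_exposure[{t!r}] outside [0, 1]")
        if self.layout not in ("paper", "random"):
            raise ValueError("layout must be 'paper' or 'random'")
        if self.layout == "random" and len(self.n_families_per_study) != 5:
            raise ValueError("n_families_per_study must have 5 entries")
        if self.swb_sd <= 0 or self.icv_sd <= 0:
            raise ValueError("swb_sd and icv_sd must be positive")


COHORT_COLUMNS = (
    ["person_id", "family_id", "zygosity_role", "study", "sex",
     "age_mri", "age_swb", "sat", "hap", "swb", "icv"]
    + [f"volume_{r}_{h}" for r in REGIONS for h in ("L", "R")]
    + ["pgs_swb", "pgs_hip_L", "pgs_hip_R", "dna", "symptom_class"]
)


def swb_composite(sat, hap) -> np.ndarray:
    """SWB composite: arithmetic mean of SAT and range-rescaled HAP.

    HAP (4-28) is mapped linearly onto the SAT range (5-35) before
    averaging, so the composite lives on the SAT scale.  The source scales
    share no natural metric; this rescaling is a documented choice (a
    composite near 24.9 on the SAT scale matches the descriptive means).
    """
    sat = np.asarray(sat, float)
    hap = np.asarray(hap, float)
    hap_s = 5.0 + (hap - 4.0) * (30.0 / 24.0)
    return (sat + hap_s) / 2.0


# ---------------------------------------------------------------------------
# pedigree skeleton
# ---------------------------------------------------------------------------

def _family_units(params: SimulationParams, rng: np.random.Generator):
    """Yield (study, [roles]) family units for the configured layout."""
    units = []
    if params.layout == "paper":
        for study, (mzp, dzp, smz, sdz, sibs, trip) in _PAPER_LAYOUT.items():
            fams = ([["MZ1", "MZ2"]] * mzp + [["DZ1", "DZ2"]] * dzp
                    + [["MZ1"]] * smz + [["DZ1"]] * sdz
                    + [["MZ1", "MZ2", "SIB"]] * trip)
            # attach extra siblings to twin families round-robin
            attach = rng.choice(len(fams), size=sibs, replace=(sibs > len(fams)))
            fams = [list(f) for f in fams]
            for a in attach:
                fams[int(a)].append("SIB")
            units.extend((study, f) for f in fams)
    else:
        for study, n_fam in zip(range(1, 6), params.n_families_per_study):
            for _ in range(n_fam):
                mz = rng.random() < params.mz_fraction
                roles = ["MZ1", "MZ2"] if mz else ["DZ1", "DZ2"]
                extra = rng.choice(len(params.sib_count_distribution),
                                   p=params.sib_count_distribution)
                roles += ["SIB"] * int(extra)
                if params.triplets and mz and rng.random() < 0.01:
                    roles.append("SIB")
                units.append((study, roles))
    return units


def _assign_sex(persons: pd.DataFrame, params: SimulationParams,
                rng: np.random.Generator) -> np.ndarray:
    """Per-study sex labels; MZ pairs are same-sex.

    Under the paper layout the exact per-study M/F counts are matched by
    choosing how many MZ pairs are male and filling the remainder among
    individually assignable persons.
    """
    sex = np.empty(len(persons), dtype=object)
    for study, grp in persons.groupby("study"):
        idx = grp.index.to_numpy()
        fam = grp["family_id"].to_numpy()
        role = grp["zygosity_role"].to_numpy()
        # only complete MZ pairs are same-sex constrained units; a single MZ
        # twin (or any DZ twin / sibling) is individually assignable
        counts = pd.Series(fam[np.isin(role, ["MZ1", "MZ2"])]).value_counts()
        mz_fams = sorted(counts[counts == 2].index)
        is_mz = np.isin(role, ["MZ1", "MZ2"]) & np.isin(fam, mz_fams)
        free_idx = idx[~is_mz]
        if params.layout == "paper":
            n_m, n_f = _PAPER_SEX[study]
            lo = max(0, int(np.ceil((n_m - len(free_idx)) / 2)))
            hi = min(len(mz_fams), n_m // 2)
            feasible = [m for m in range(lo, hi + 1)
                        if 0 <= n_m - 2 * m <= len(free_idx)]
            m_pairs = int(rng.choice(feasible))
            m_free = n_m - 2 * m_pairs
        else:
            m_pairs = int(rng.binomial(len(mz_fams), 0.5))
            m_free = int(rng.binomial(len(free_idx), 0.5))
        male_fams = set(rng.choice(mz_fams, size=m_pairs, replace=False)
                        if m_pairs else [])
        male_free = set(rng.choice(free_idx, size=m_free, replace=False)
                        if m_free else [])
        for pos, i in enumerate(idx):
            if is_mz[pos]:
                sex[i] = "M" if fam[pos] in male_fams else "F"
            else:
                sex[i] = "M" if i in male_free else "F"
    return sex


def _truncated_normal(rng, mean, sd, low, high, size):
    out = mean + sd * rng.standard_normal(size)
    for _ in range(100):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
    return np.clip(out, low, high)


# ---------------------------------------------------------------------------
# latent draws with family sharing
# ---------------------------------------------------------------------------

def _additive_latent(rng, fam_codes, gid_codes):
    """Additive-genetic latent: corr 1 within MZ, 0.5 within DZ/sib dyads."""
    a_fam = rng.standard_normal(fam_codes.max() + 1)
    a_ind = rng.standard_normal(gid_codes.max() + 1)
    return np.sqrt(0.5) * a_fam[fam_codes] + np.sqrt(0.5) * a_ind[gid_codes]


def _dominance_latent(rng, fam_codes, gid_codes):
    """Dominance latent: corr 1 within MZ, 0.25 within DZ pairs."""
    d_fam = rng.standard_normal(fam_codes.max() + 1)
    d_ind = rng.standard_normal(gid_codes.max() + 1)
    return 0.5 * d_fam[fam_codes] + np.sqrt(0.75) * d_ind[gid_codes]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(params: SimulationParams | None = None,
                    *, return_latents: bool = False):
    """Generate a cohort table (one row per person).

    With ``return_latents`` the per-person additive-genetic and
    environmental latents are returned alongside, for tests that check the
    planted family structure directly.
    """
    params = SimulationParams() if params is None else params
    params.validate()
    rng = np.random.default_rng(params.seed)

    units = _family_units(params, rng)
    rows = []
    fam_counter = 0
    for study, roles in units:
        fam_counter += 1
        fam_id = f"F{fam_counter:05d}"
        for m, role in enumerate(roles, start=1):
            rows.append({"person_id": f"S{study}{fam_id}P{m}",
                         "family_id": fam_id, "zygosity_role": role,
                         "study": study})
    persons = pd.DataFrame(rows)
    n = len(persons)

    persons["sex"] = _assign_sex(persons, params, rng)

    # genetic-identity codes: MZ co-twins share one code
    fam_codes = pd.factorize(persons["family_id"])[0]
    gid = []
    for fam, grp in persons.groupby("family_id", sort=False):
        for i, role in zip(grp.index, grp["zygosity_role"]):
            gid.append((fam, "MZ") if role in ("MZ1", "MZ2") else (fam, i))
    gid_codes = pd.factorize(pd.Series(gid, index=persons.index))[0]

    # ages: twins share age at MRI; siblings differ by a few years
    age_mri = np.empty(n)
    for study, grp in persons.groupby("study"):
        mean, sd, lo, hi = params.age_ranges_per_study[study]
        for fam, g in grp.groupby("family_id"):
            base = float(_truncated_normal(rng, mean, sd, lo, hi, 1)[0])
            for i, role in zip(g.index, g["zygosity_role"]):
                if role == "SIB":
                    off = rng.uniform(1.5, 4.0) * rng.choice([-1.0, 1.0])
                    age_mri[i] = float(np.clip(base + off, lo, hi))
                else:
                    age_mri[i] = base
    delays = persons["study"].map(params.swb_delay_per_study).to_numpy(float)
    sd_by_study = persons["study"].map(
        {s: v[1] for s, v in params.age_ranges_per_study.items()}
    ).to_numpy(float)
    age_swb = age_mri + delays + 0.3 * sd_by_study * rng.standard_normal(n)

    # latent factors
    h2v = params.h2_targets.get("volume", 0.76)
    d2v = params.d2_targets.get("volume", 0.0)
    h2s = params.h2_targets.get("swb", 0.44)
    d2s = params.d2_targets.get("swb", 0.0)
    h2i = params.h2_targets.get("icv", 0.80)

    g_common = _additive_latent(rng, fam_codes, gid_codes)
    g_region = {r: _additive_latent(rng, fam_codes, gid_codes)
                for r in REGIONS}
    g_trait = {(r, h): _additive_latent(rng, fam_codes, gid_codes)
               for r in REGIONS for h in ("L", "R")}
    g_icv = _additive_latent(rng, fam_codes, gid_codes)
    g_swb = _additive_latent(rng, fam_codes, gid_codes)
    e_region = {r: rng.standard_normal(n) for r in REGIONS}
    e_trait = {(r, h): rng.standard_normal(n)
               for r in REGIONS for h in ("L", "R")}
    e_icv = rng.standard_normal(n)
    e_swb = rng.standard_normal(n)
    if d2v > 0:
        d_trait = {(r, h): _dominance_latent(rng, fam_codes, gid_codes)
                   for r in REGIONS for h in ("L", "R")}
    if d2s > 0:
        d_swb = _dominance_latent(rng, fam_codes, gid_codes)

    wa = np.sqrt(params.genetic_common)
    wb = np.sqrt(params.genetic_lr_extra)
    wc = np.sqrt(max(0.0, 1.0 - params.genetic_common
                     - params.genetic_lr_extra))
    we_r = np.sqrt(params.env_lr)
    we_u = np.sqrt(1.0 - params.env_lr)

    icv_core = np.sqrt(h2i) * g_icv + np.sqrt(1.0 - h2i) * e_icv
    vfrac = params.icv_volume_fraction
    male = (persons["sex"] == "M").to_numpy(float)

    a_vol, e_vol, full_core = {}, {}, {}
    vols = {}
    for r in REGIONS:
        for h in ("L", "R"):
            a = wa * g_common + wb * g_region[r] + wc * g_trait[(r, h)]
            e = we_r * e_region[r] + we_u * e_trait[(r, h)]
            core = np.sqrt(h2v) * a + np.sqrt(max(0.0, 1 - h2v - d2v)) * e
            if d2v > 0:
                core = core + np.sqrt(d2v) * d_trait[(r, h)]
            full = np.sqrt(1 - vfrac) * core + np.sqrt(vfrac) * icv_core
            a_vol[(r, h)], e_vol[(r, h)], full_core[(r, h)] = a, e, full
            vols[f"volume_{r}_{h}"] = (
                params.vol_means[r] + params.vol_sds[r] * full
                + params.sex_effect_vol * params.vol_sds[r] * male)
    icv = params.icv_mean + params.icv_sd * icv_core

    # planted concave hippocampus -> SWB link
    hip_bar = 0.5 * (full_core[("hippocampus", "L")]
                     + full_core[("hippocampus", "R")])
    hz = hip_bar / hip_bar.std(ddof=0)
    planted = params.lin_beta * hz + params.quad_beta * (hz ** 2 - 1.0)

    rg, re = params.rg_swb_vol, params.re_swb_vol
    a_hip_norm = (a_vol[("hippocampus", "L")] + a_vol[("hippocampus", "R")]) \
        / np.sqrt(2.0 + 2.0 * (params.genetic_common
                               + params.genetic_lr_extra))
    e_hip_norm = (e_vol[("hippocampus", "L")] + e_vol[("hippocampus", "R")]) \
        / np.sqrt(2.0 + 2.0 * params.env_lr)
    a_swb = rg * a_hip_norm + np.sqrt(1 - rg ** 2) * g_swb
    e_swb_c = re * e_hip_norm + np.sqrt(1 - re ** 2) * e_swb
    swb_core = np.sqrt(h2s) * a_swb + np.sqrt(max(0.0, 1 - h2s - d2s)) * e_swb_c
    if d2s > 0:
        swb_core = swb_core + np.sqrt(d2s) * d_swb

    resid_scale = np.sqrt(max(params.swb_sd ** 2 - planted.var(),
                              0.25 * params.swb_sd ** 2))
    swb_latent = (params.swb_mean + resid_scale * swb_core + planted
                  + params.sex_effect_swb * male)

    # split into SAT and HAP so the composite rule reproduces swb exactly
    delta = params.sat_hap_split_sd * rng.standard_normal(n)
    sat = np.clip(swb_latent + delta, 5.0, 35.0)
    hap_s = np.clip(2.0 * swb_latent - sat, 5.0, 35.0)
    hap = 4.0 + (hap_s - 5.0) * (24.0 / 30.0)
    swb = swb_composite(sat, hap)

    # polygenic scores: share of the additive latent plus independent noise
    def _pgs(a_latent, r2, h2):
        q = min(1.0, r2 / h2) if h2 > 0 else 0.0
        return np.sqrt(q) * a_latent + np.sqrt(1 - q) * rng.standard_normal(n)

    pgs_swb = _pgs(a_swb, params.pgs_r2_exposure.get("swb", 0.015), h2s)
    pgs_hip_l = _pgs(a_vol[("hippocampus", "L")],
                     params.pgs_r2_exposure.get("hip", 0.025), h2v)
    pgs_hip_r = _pgs(a_vol[("hippocampus", "R")],
                     params.pgs_r2_exposure.get("hip", 0.025), h2v)

    dna = np.zeros(n, dtype=bool)
    n_dna = min(params.dna_n, n) if params.layout == "paper" \
        else int(round(n * min(1.0, params.dna_n / 724)))
    dna[rng.choice(n, size=n_dna, replace=False)] = True

    cohort = pd.DataFrame({
        "person_id": persons["person_id"], "family_id": persons["family_id"],
        "zygosity_role": persons["zygosity_role"], "study": persons["study"],
        "sex": persons["sex"], "age_mri": np.round(age_mri, 2),
        "age_swb": np.round(age_swb, 2), "sat": sat, "hap": hap, "swb": swb,
        "icv": icv, **vols,
        "pgs_swb": pgs_swb, "pgs_hip_L": pgs_hip_l, "pgs_hip_R": pgs_hip_r,
        "dna": dna, "symptom_class": 1,
    })
    for j in range(params.n_pc_covariates):
        cohort[f"pc_{j + 1}"] = rng.standard_normal(n)

    if params.selection_spec:
        cohort = apply_symptom_selection(cohort, params)

    if return_latents:
        latents = {
            "a_swb": a_swb, "e_swb": e_swb_c, "swb_core": swb_core,
            "a_hip_L": a_vol[("hippocampus", "L")],
            "a_hip_R": a_vol[("hippocampus", "R")],
            "e_hip_L": e_vol[("hippocampus", "L")],
            "e_hip_R": e_vol[("hippocampus", "R")],
            "hz": hz, "planted": planted,
            "fam_codes": fam_codes, "gid_codes": gid_codes,
        }
        return cohort, latents
    return cohort


def apply_symptom_selection(cohort: pd.DataFrame,
                            params: SimulationParams,
                            studies: list[int] | None = None) -> pd.DataFrame:
    """Assign symptom classes 0 (low) / 1 (unselected) / 2 (high).

    A latent symptom score correlated with SWB (``symptom_swb_corr``,
    negative by default so high-symptom subjects have low well-being) is cut
    within each selected study either at fixed group counts or at quantiles.
    Studies without a selection rule keep class 1 everywhere.
    """
    cohort = cohort.copy()
    cohort["symptom_class"] = 1
    spec = params.selection_spec or {}
    studies = sorted(spec) if studies is None else list(studies)
    for s in studies:
        if s not in spec:
            raise ValueError(f"symptom selection requested for study {s} "
                             f"but no selection rule is defined")
    rng = np.random.default_rng(np.random.SeedSequence(
        [params.seed, 911]).generate_state(1)[0])
    rho = params.symptom_swb_corr
    for s in studies:
        rule = spec[s]
        grp = cohort[cohort["study"] == s]
        if grp.empty:
            continue
        swb = grp["swb"].to_numpy(float)
        swb_z = (swb - swb.mean()) / swb.std(ddof=1)
        sym = rho * swb_z + np.sqrt(1 - rho ** 2) * \
            rng.standard_normal(len(grp))
        order = np.argsort(-sym, kind="stable")      # descending symptoms
        cls = np.ones(len(grp), dtype=int)
        if rule.n_high is not None or rule.n_low is not None:
            nh = int(rule.n_high or 0)
            nl = int(rule.n_low or 0)
            if nh + nl > len(grp):
                raise ValueError(f"selection counts exceed study {s} size")
            cls[order[:nh]] = 2
            if nl:
                cls[order[-nl:]] = 0
        else:
            qh = 1.0 - (rule.q_high or 0.0)
            ql = rule.q_low or 0.0
            hi_cut = np.quantile(sym, qh)
            lo_cut = np.quantile(sym, ql)
            cls[sym >= hi_cut] = 2
            cls[sym <= lo_cut] = 0
        cohort.loc[grp.index, "symptom_class"] = cls
    return cohort


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SummaryStatsPair:
    """Per-SNP Z-scores for two traits plus LD scores and sample sizes."""

    table: pd.DataFrame        # columns: snp, ld_score, z1, z2
    n1: int
    n2: int
    m: int
    true_h2_1: float
    true_h2_2: float
    true_rg: float


def simulate_gwas_pair(m: int, h2_1: float, h2_2: float, rg: float,
                       n1: int, n2: int, seed: int,
                       *, ld_mean: float = 10.0) -> SummaryStatsPair:
    """Bivariate GWAS Z-scores under the LD-score regression model.

    For SNP j with LD score l_j, ``E[z_i^2] = N_i h2_i l_j / M + 1`` and
    ``E[z1 z2] = sqrt(N1 N2) rho_g l_j / M`` with
    ``rho_g = rg sqrt(h2_1 h2_2)`` (no sample overlap, intercepts 1 and 0).
    """
    if m < 1000:
        raise ValueError("need at least 1000 SNPs")
    if abs(rg) > 1:
        raise ValueError("|rg| must be <= 1")
    for h2 in (h2_1, h2_2):
        if not 0.0 <= h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ell = 1.0 + rng.exponential(max(ld_mean - 1.0, 0.0), size=m)
    c11 = 1.0 + n1 * h2_1 * ell / m
    c22 = 1.0 + n2 * h2_2 * ell / m
    c12 = np.sqrt(n1 * n2) * rg * np.sqrt(h2_1 * h2_2) * ell / m
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21 ** 2, 1e-12))
    u = rng.standard_normal((m, 2))
    z1 = l11 * u[:, 0]
    z2 = l21 * u[:, 0] + l22 * u[:, 1]
    table = pd.DataFrame({"snp": [f"rs{j + 1}" for j in range(m)],
                          "ld_score": ell, "z1": z1, "z2": z2})
    return SummaryStatsPair(table=table, n1=n1, n2=n2, m=m,
                            true_h2_1=h2_1, true_h2_2=h2_2, true_rg=rg)


# ---------------------------------------------------------------------------
# direct twin-pair simulation (for covariance-structure fitting tests)
# ---------------------------------------------------------------------------

def simulate_twin_pairs(sigma_a, sigma_d, sigma_e, n_mz: int, n_dz: int,
                        seed: int, traits: list[str] | None = None) -> TwinData:
    """Draw MZ/DZ pair vectors from the biometric covariance structure."""
    sigma_a = np.atleast_2d(np.asarray(sigma_a, float))
    p = sigma_a.shape[0]
    traits = traits or [f"t{i + 1}" for i in range(p)]
    rng = np.random.default_rng(seed)

    def draw(zyg, count):
        cov = expected_twin_cov(sigma_a, sigma_d, sigma_e, zyg)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2 * p))
        return rng.standard_normal((count, 2 * p)) @ chol.T

    return TwinData(mz=draw("MZ", n_mz), dz=draw("DZ", n_dz),
                    traits=list(traits),
                    mz_cov=np.empty((n_mz, 2, 0)),
                    dz_cov=np.empty((n_dz, 2, 0)),
                    covariate_names=[])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    """Write the cohort as TSV with 'NA' for missing values."""
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA", columns=cols)


def read_cohort_tsv(path) -> pd.DataFrame:
    """Read a cohort TSV, validating header and pedigree tokens."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    required = [c for c in COHORT_COLUMNS if not c.startswith("pc_")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    valid = {"MZ1", "MZ2", "DZ1", "DZ2", "SIB"}
    bad = ~df["zygosity_role"].isin(valid)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"malformed zygosity token "
                         f"{df.loc[df.index[row], 'zygosity_role']!r} "
                         f"at data row {row + 1}")
    if df["dna"].dtype == object:
        df["dna"] = df["dna"].map({"True": True, "False": False})
    df["dna"] = df["dna"].astype(bool)
    return df


def write_sumstats(pair: SummaryStatsPair, prefix) -> None:
    """Write sumstats-style TSVs (SNP, Z, N) plus an LD-score TSV (SNP, L2)."""
    t = pair.table
    for i in (1, 2):
        n = pair.n1 if i == 1 else pair.n2
        out = pd.DataFrame({"SNP": t["snp"], "Z": t[f"z{i}"], "N": n})
        out.to_csv(f"{prefix}.trait{i}.sumstats.tsv", sep="\t", index=False)
    ld = pd.DataFrame({"SNP": t["snp"], "L2": t["ld_score"]})
    ld.to_csv(f"{prefix}.ldscore.tsv", sep="\t", index=False)
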