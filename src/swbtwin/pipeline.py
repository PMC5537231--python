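"""Pipeline orchestration: simulate -> associate -> post-hoc -> meta -> MR
-> twin model -> LDSC, driven by a single YAML config and one seed.

Every stage writes its tables (TSV) and fit records (JSON) under the output
directory together with a run log recording the seed, alpha levels and
design-decision toggles in effect.  All randomness flows from the config
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lmm, ldsc, meta, mr, simulate, twin

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_cohort", "write_table",
           "twin_model_report", "plot_association"]

_ALL_STAGES = ("simulate", "associate", "posthoc", "meta", "mr", "twin",
               "ldsc")


@dataclass
class PipelineConfig:
    """Run configuration; defaults reproduce the five-study-scale cohort."""

    seed: int = 0
    output_dir: str = "swbtwin_out"
    cohort_path: str | None = None          # None -> simulate
    stages: tuple = _ALL_STAGES
    simulation: dict = field(default_factory=dict)  # SimulationParams overrides
    alpha_scan: float = 0.05 / 14
    alpha_interaction: float = 0.05 / 4
    alpha_twin: float = 0.01
    region: str = "hippocampus"
    ldsc_m: int = 20000
    ldsc_h2_1: float = 0.04
    ldsc_h2_2: float = 0.25
    ldsc_rg: float = -0.07
    ldsc_n1: int = 298000
    ldsc_n2: int = 13000

    def validate(self) -> None:
        for a in (self.alpha_scan, self.alpha_interaction, self.alpha_twin):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must lie in (0, 1)")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.cohort_path is not None and \
                not Path(self.cohort_path).exists():
            raise ValueError(f"cohort file not found: {self.cohort_path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort TSV (see simulate.read_cohort_tsv)."""
    return simulate.read_cohort_tsv(path)


def write_table(obj: pd.DataFrame, path) -> None:
    """Write a result table as TSV with NA markers."""
    obj.to_csv(path, sep="\t", index=False, na_rep="NA")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def twin_model_report(cohort: pd.DataFrame, region: str = "hippocampus",
                      *, alpha: float = 0.01) -> dict:
    """Five-trait twin-model stage: saturated, ADE, AE fits plus LRTs.

    Traits are SWB, the Z-scored left/right volumes and their squares (the
    squares taken after covariate-free standardization).  Reports MZ/DZ
    correlations, AE heritabilities, genetic/environmental correlations and
    the omnibus tests of the SWB-volume cross correlations.
    """
    df = cohort.copy()
    zl = lmm.zscore(df[f"volume_{region}_L"].to_numpy(float))
    zr = lmm.zscore(df[f"volume_{region}_R"].to_numpy(float))
    df["zvol_L"], df["zvol_R"] = zl, zr
    df["zvol_L_sq"], df["zvol_R_sq"] = zl ** 2, zr ** 2
    traits = ["swb", "zvol_L", "zvol_R", "zvol_L_sq", "zvol_R_sq"]
    data = twin.assemble_twin_pairs(df, traits,
                                    covariates=("study", "age_mri", "sex"))
    # restrict to complete pairs so all models share one likelihood basis
    # (the saturated baseline has no closed form for partially observed
    # pairs); full-information fitting of incomplete pairs remains available
    # through fit_biometric directly
    keep_mz = ~np.isnan(data.mz).any(axis=1)
    keep_dz = ~np.isnan(data.dz).any(axis=1)
    data = twin.TwinData(mz=data.mz[keep_mz], dz=data.dz[keep_dz],
                         traits=data.traits, mz_cov=data.mz_cov[keep_mz],
                         dz_cov=data.dz_cov[keep_dz],
                         covariate_names=data.covariate_names)
    sat = twin.fit_saturated(data)
    ade = twin.fit_biometric(data, "ADE")
    ae = twin.fit_biometric(data, "AE")
    chi_ade, df_ade, p_ade = twin.likelihood_ratio_test(sat, ade)
    chi_d, df_d, p_d = twin.likelihood_ratio_test(ade, ae)
    ae_rg0 = twin.fit_biometric(data, "AE", zero_swb_cross="A")
    ae_re0 = twin.fit_biometric(data, "AE", zero_swb_cross="E")
    chi_rg, df_rg, p_rg = twin.likelihood_ratio_test(ae, ae_rg0)
    chi_re, df_re, p_re = twin.likelihood_ratio_test(ae, ae_re0)
    corr = sat.twin_correlations()
    report = {
        "traits": traits,
        "n_mz_pairs": int(data.mz.shape[0]),
        "n_dz_pairs": int(data.dz.shape[0]),
        "twin_correlations": corr.to_dict(orient="records"),
        "h2_ae": dict(zip(traits, ae.h2)),
        "rg_ae": ae.rg.tolist(),
        "re_ae": ae.re.tolist(),
        "loglik": {"saturated": sat.loglik, "ADE": ade.loglik,
                   "AE": ae.loglik},
        "n_parameters": {"saturated": sat.n_parameters,
                         "ADE": ade.n_parameters, "AE": ae.n_parameters},
        "lrt_ade_vs_saturated": {"chi2": chi_ade, "df": df_ade, "p": p_ade},
        "lrt_drop_dominance": {"chi2": chi_d, "df": df_d, "p": p_d,
                               "boundary_caveat": True},
        "omnibus_genetic_cross": {"chi2": chi_rg, "df": df_rg, "p": p_rg,
                                  "significant": p_rg < alpha},
        "omnibus_environmental_cross": {"chi2": chi_re, "df": df_re,
                                        "p": p_re,
                                        "significant": p_re < alpha},
        "alpha": alpha,
    }
    table6 = corr.merge(
        pd.DataFrame({"trait": traits, "h2": ae.h2}), on="trait",
        suffixes=("_sat", "_ae"))
    return report, table6


def plot_association(cohort: pd.DataFrame, region: str, out_path) -> None:
    """Scatter of SWB against Z-scored volumes with fitted quadratic curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, hemi in zip(axes, ("L", "R")):
        sub = cohort.dropna(subset=[f"volume_{region}_{hemi}", "swb"])
        z = lmm.zscore(sub[f"volume_{region}_{hemi}"].to_numpy(float))
        y = sub["swb"].to_numpy(float)
        for s in sorted(sub["study"].unique()):
            mask = (sub["study"] == s).to_numpy()
            ax.scatter(z[mask], y[mask], s=6, alpha=0.5, label=f"study {s}")
        coef = np.polyfit(z, y, 2)
        grid = np.linspace(z.min(), z.max(), 100)
        ax.plot(grid, np.polyval(coef, grid), "k-", lw=2)
        ax.set_xlabel(f"{region} {hemi} (Z)")
    axes[0].set_ylabel("SWB")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the summary report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed,
                    "alphas": {"scan": config.alpha_scan,
                               "interaction": config.alpha_interaction,
                               "twin": config.alpha_twin},
                    "df_method": "satterthwaite",
                    "estimation": "ML",
                    "python": platform.python_version(),
                    "numpy": np.__version__,
                    "stages": list(config.stages)}
    stage = "setup"
    try:
        if config.cohort_path is not None:
            stage = "read_cohort"
            cohort = read_cohort(config.cohort_path)
        else:
            stage = "simulate"
            params = simulate.SimulationParams(seed=config.seed,
                                               **config.simulation)
            cohort = simulate.simulate_cohort(params)
        if "simulate" in config.stages or config.cohort_path is None:
            simulate.write_cohort_tsv(cohort, out / "cohort.tsv")
        report["cohort"] = {
            "n": int(len(cohort)),
            "per_study": {int(s): int(c) for s, c in
                          cohort["study"].value_counts().sort_index()
                          .items()},
            "males": int((cohort["sex"] == "M").sum()),
            "females": int((cohort["sex"] == "F").sum()),
        }

        if "associate" in config.stages:
            stage = "associate"
            scan = lmm.association_scan(cohort, alpha=config.alpha_scan)
            write_table(scan, out / "association.tsv")
            _dump_json(scan.to_dict(orient="records"),
                       out / "association.json")
            sig = scan[scan["linear_significant"]
                       | scan["quadratic_significant"]]
            report["association"] = {
                "alpha": config.alpha_scan,
                "n_rows": int(len(scan)),
                "significant_regions": sorted(set(
                    f"{r.region}_{r.hemisphere}"
                    for r in sig.itertuples())),
            }
            strata = lmm.swb_by_volume_strata(cohort, config.region)
            write_table(strata, out / "swb_by_volume_strata.tsv")
            report["swb_by_volume_strata"] = strata.to_dict(orient="records")

        if "posthoc" in config.stages:
            stage = "posthoc"
            frames = []
            for variant in ("outcome_sat", "outcome_hap", "drop_quadratic",
                            "raw_volumes", "add_age_swb",
                            "add_symptom_score"):
                frames.append(lmm.posthoc_battery(cohort, config.region,
                                                  variant))
            write_table(pd.concat(frames, ignore_index=True),
                        out / "posthoc.tsv")
            inter = lmm.posthoc_battery(
                cohort, config.region, "study_interactions",
                interaction_alpha=config.alpha_interaction)
            write_table(inter, out / "posthoc_interactions.tsv")
            report["posthoc_variants"] = 6

        if "meta" in config.stages:
            stage = "meta"
            table4 = meta.meta_table(cohort, config.region,
                                     alpha=config.alpha_interaction)
            write_table(table4, out / "meta.tsv")
            pooled = table4[table4["study"] == "pooled"]
            report["meta_pooled"] = pooled[
                ["hemisphere", "term", "estimate", "se", "p"]
            ].to_dict(orient="records")

        if "mr" in config.stages:
            stage = "mr"
            table5 = mr.bidirectional_mr(cohort, config.region)
            write_table(table5, out / "mr.tsv")
            _dump_json(table5.to_dict(orient="records"), out / "mr.json")
            report["mr"] = table5[["direction", "hemisphere", "df", "F", "p"]
                                  ].to_dict(orient="records")

        if "twin" in config.stages:
            stage = "twin"
            twin_report, table6 = twin_model_report(
                cohort, config.region, alpha=config.alpha_twin)
            _dump_json(twin_report, out / "twin.json")
            write_table(table6, out / "twin_correlations.tsv")
            report["twin"] = {
                "h2_ae": twin_report["h2_ae"],
                "omnibus_genetic_cross":
                    twin_report["omnibus_genetic_cross"],
                "omnibus_environmental_cross":
                    twin_report["omnibus_environmental_cross"],
            }

        if "ldsc" in config.stages:
            stage = "ldsc"
            pair = simulate.simulate_gwas_pair(
                config.ldsc_m, config.ldsc_h2_1, config.ldsc_h2_2,
                config.ldsc_rg, config.ldsc_n1, config.ldsc_n2,
                seed=config.seed + 104729)
            simulate.write_sumstats(pair, str(out / "gwas"))
            res = ldsc.rg_regression(pair)
            record = {"h2_1": res.h2_1, "h2_2": res.h2_2, "rg": res.rg,
                      "rg_se": res.rg_se, "Z": res.z, "p": res.p,
                      "intercept_1": res.intercept_1,
                      "intercept_2": res.intercept_2,
                      "intercept_cross": res.intercept_cross,
                      "true_rg": pair.true_rg}
            _dump_json(record, out / "ldsc.json")
            report["ldsc"] = record
    except Exception as err:
        _dump_json({"failed_stage": stage, "error": str(err),
                    "type": type(err).__name__}, out / "error.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    _dump_json(report, out / "report.json")
    return report
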