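"""Generator tests: pedigree structure, planted latent sharing, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swbtwin import (SelectionRule, SimulationParams, apply_symptom_selection,
                     simulate_cohort, simulate_gwas_pair, simulate_twin_pairs,
                     swb_composite)
from swbtwin.simulate import read_cohort_tsv, write_cohort_tsv


class TestCohortStructure:
    def test_paper_layout_counts(self, default_cohort):
        c = default_cohort
        assert len(c) == 724
        assert c["study"].value_counts().sort_index().tolist() == \
            [58, 244, 58, 130, 234]
        assert int((c["sex"] == "M").sum()) == 302
        assert int((c["sex"] == "F").sum()) == 422
        assert not c["person_id"].duplicated().any()

    def test_same_seed_reproduces_table(self):
        a = simulate_cohort(SimulationParams(seed=5))
        b = simulate_cohort(SimulationParams(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_families_have_at_most_one_twin_pair(self, default_cohort):
        for fam, grp in default_cohort.groupby("family_id"):
            roles = grp["zygosity_role"].tolist()
            n_twins = sum(r in ("MZ1", "MZ2", "DZ1", "DZ2") for r in roles)
            assert n_twins <= 2
            mz = [r for r in roles if r.startswith("MZ")]
            dz = [r for r in roles if r.startswith("DZ")]
            assert not (mz and dz)

    def test_mz_pairs_same_sex(self, default_cohort):
        for _, grp in default_cohort.groupby("family_id"):
            mz = grp[grp["zygosity_role"].isin(["MZ1", "MZ2"])]
            if len(mz) == 2:
                assert mz["sex"].nunique() == 1

    def test_volumes_and_icv_positive(self, default_cohort):
        vol_cols = [c for c in default_cohort.columns
                    if c.startswith("volume_")] + ["icv"]
        assert (default_cohort[vol_cols] > 0).all().all()

    def test_ages_strongly_correlated(self, default_cohort):
        r = np.corrcoef(default_cohort["age_mri"],
                        default_cohort["age_swb"])[0, 1]
        assert r >= 0.9

    def test_dna_subsample_size(self, default_cohort):
        assert int(default_cohort["dna"].sum()) == 636

    def test_invalid_params_name_offending_field(self):
        with pytest.raises(ValueError, match="h2_targets"):
            simulate_cohort(SimulationParams(h2_targets={"swb": 1.4}))
        with pytest.raises(ValueError, match="h2\\+d2"):
            simulate_cohort(SimulationParams(d2_targets={"volume": 0.5}))
        with pytest.raises(ValueError, match="rg_swb_vol"):
            simulate_cohort(SimulationParams(rg_swb_vol=1.5))
        with pytest.raises(ValueError, match="non-PSD"):
            simulate_cohort(SimulationParams(genetic_common=0.7,
                                             genetic_lr_extra=0.7))


class TestPlantedStructure:
    def test_swb_composite_rule_exact(self, default_cohort):
        recon = swb_composite(default_cohort["sat"], default_cohort["hap"])
        np.testing.assert_allclose(recon, default_cohort["swb"], atol=1e-12)

    def test_mz_latents_identical_dz_sib_shared(self):
        cohort, lat = simulate_cohort(
            SimulationParams(layout="random",
                             n_families_per_study=(500,) * 5,
                             selection_spec={}, seed=11),
            return_latents=True)
        a = lat["a_swb"]
        fam = cohort["family_id"].to_numpy()
        role = cohort["zygosity_role"].to_numpy()
        mz_diffs, dz_pairs = [], []
        by_fam = {}
        for i in range(len(cohort)):
            by_fam.setdefault(fam[i], []).append(i)
        for idx in by_fam.values():
            rs = {role[i]: i for i in idx}
            if "MZ1" in rs and "MZ2" in rs:
                mz_diffs.append(abs(a[rs["MZ1"]] - a[rs["MZ2"]]))
            if "DZ1" in rs and "DZ2" in rs:
                dz_pairs.append((a[rs["DZ1"]], a[rs["DZ2"]]))
        assert max(mz_diffs) < 1e-12               # MZ genetic corr exactly 1
        dz = np.asarray(dz_pairs)
        r = np.corrcoef(dz[:, 0], dz[:, 1])[0, 1]
        se = 1.0 / np.sqrt(len(dz))                # rough MC standard error
        assert abs(r - 0.5) < 3 * se

    def test_twin_phenotype_correlations_match_h2(self):
        # h2 = 0.75 trait: MZ correlation ~ 0.75, DZ ~ 0.375
        data = simulate_twin_pairs([[0.75]], [[0.0]], [[0.25]],
                                   10_000, 10_000, seed=9)
        r_mz = np.corrcoef(data.mz[:, 0], data.mz[:, 1])[0, 1]
        r_dz = np.corrcoef(data.dz[:, 0], data.dz[:, 1])[0, 1]
        se = 1.0 / np.sqrt(10_000)
        assert abs(r_mz - 0.75) < 3 * se * (1 - 0.75 ** 2)
        assert abs(r_dz - 0.375) < 3 * se * (1 - 0.375 ** 2)

    def test_phenotypic_variance_near_target_at_large_n(self):
        params = SimulationParams(layout="random",
                                  n_families_per_study=(1000,) * 5,
                                  selection_spec={}, seed=13)
        c = simulate_cohort(params)
        assert len(c) >= 10_000
        assert abs(c["swb"].var() / params.swb_sd ** 2 - 1) < 0.05
        v = c["volume_hippocampus_L"].var()
        assert abs(v / params.vol_sds["hippocampus"] ** 2 - 1) < 0.05

    def test_concave_link_orders_volume_strata(self):
        c = simulate_cohort(SimulationParams(
            layout="random", n_families_per_study=(1000,) * 5,
            selection_spec={}, seed=17))
        z = (c["volume_hippocampus_L"] - c["volume_hippocampus_L"].mean()) \
            / c["volume_hippocampus_L"].std()
        low = c.loc[z <= -0.5, "swb"].mean()
        mid = c.loc[(z > -0.5) & (z < 0.5), "swb"].mean()
        high = c.loc[z >= 0.5, "swb"].mean()
        assert low < mid <= high + 0.2


class TestSymptomSelection:
    def test_disabled_selection_all_unselected(self, small_cohort):
        assert (small_cohort["symptom_class"] == 1).all()

    def test_default_counts_match_design(self, default_cohort):
        counts = default_cohort.groupby(
            ["study", "symptom_class"]).size().unstack(fill_value=0)
        assert counts.loc[1, 2] == 23 and counts.loc[1, 0] == 35
        assert counts.loc[2, 2] == 75 and counts.loc[2, 0] == 167
        assert counts.loc[3, 2] == 23 and counts.loc[3, 0] == 35
        assert (default_cohort.loc[default_cohort["study"].isin([4, 5]),
                                   "symptom_class"] == 1).all()

    def test_high_class_swb_below_low_class(self, default_cohort):
        for s in (1, 2, 3):
            grp = default_cohort[default_cohort["study"] == s]
            assert grp.loc[grp["symptom_class"] == 2, "swb"].mean() < \
                grp.loc[grp["symptom_class"] == 0, "swb"].mean()

    def test_decile_cut_gap_matches_truncated_normal_oracle(self):
        rho = -0.5
        params = SimulationParams(
            layout="random", n_families_per_study=(600, 5, 5, 5, 5),
            symptom_swb_corr=rho,
            selection_spec={1: SelectionRule(q_high=0.1, q_low=0.1)},
            seed=23)
        c = simulate_cohort(params)
        grp = c[c["study"] == 1]
        mu, sd = grp["swb"].mean(), grp["swb"].std()
        # E[swb | symptom in upper decile] = mu + sd * rho * lambda(c)
        cut = stats.norm.ppf(0.9)
        lam = stats.norm.pdf(cut) / stats.norm.sf(cut)
        expect_high = mu + sd * rho * lam
        expect_low = mu - sd * rho * lam
        got_high = grp.loc[grp["symptom_class"] == 2, "swb"].mean()
        got_low = grp.loc[grp["symptom_class"] == 0, "swb"].mean()
        n_grp = (grp["symptom_class"] == 2).sum()
        mc = 3 * sd / np.sqrt(n_grp)
        assert abs(got_high - expect_high) < mc
        assert abs(got_low - expect_low) < mc

    def test_selection_without_rule_errors(self, default_cohort):
        params = SimulationParams(seed=0)
        with pytest.raises(ValueError, match="study 4"):
            apply_symptom_selection(default_cohort, params, studies=[4])


class TestGwasPair:
    def test_zero_rg_zero_mean_cross_product(self):
        pair = simulate_gwas_pair(20_000, 0.3, 0.3, 0.0, 30_000, 30_000,
                                  seed=1)
        cross = (pair.table["z1"] * pair.table["z2"]).mean()
        # per-SNP products have heavy tails; 3 empirical SEs
        se = (pair.table["z1"] * pair.table["z2"]).std() / np.sqrt(pair.m)
        assert abs(cross) < 3 * se

    def test_marginal_z2_follows_ld_expectation(self):
        pair = simulate_gwas_pair(20_000, 0.25, 0.25, 0.0, 50_000, 50_000,
                                  seed=2)
        t = pair.table
        slope = np.polyfit(t["ld_score"], t["z1"] ** 2, 1)[0]
        h2 = slope * pair.m / pair.n1
        assert abs(h2 - 0.25) < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="rg"):
            simulate_gwas_pair(2000, 0.3, 0.3, 1.5, 1000, 1000, seed=0)
        with pytest.raises(ValueError, match="1000"):
            simulate_gwas_pair(500, 0.3, 0.3, 0.0, 1000, 1000, seed=0)
        pair = simulate_gwas_pair(2000, 0.3, 0.3, 0.5, 1000, 1000, seed=0)
        assert (pair.table["ld_score"] >= 1.0).all()
        assert np.isfinite(pair.table[["z1", "z2"]]).all().all()


class TestIo:
    def test_round_trip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.tsv"
        write_cohort_tsv(small_cohort, path)
        back = read_cohort_tsv(path)
        pd.testing.assert_frame_equal(
            back, small_cohort.reset_index(drop=True), check_dtype=False)

    def test_na_preserved(self, small_cohort, tmp_path):
        c = small_cohort.copy()
        c.loc[c.index[0], "age_swb"] = np.nan
        path = tmp_path / "cohort.tsv"
        write_cohort_tsv(c, path)
        back = read_cohort_tsv(path)
        assert np.isnan(back.loc[0, "age_swb"])

    def test_malformed_zygosity_rejected_with_row(self, small_cohort,
                                                  tmp_path):
        c = small_cohort.copy()
        c.loc[c.index[2], "zygosity_role"] = "XX"
        path = tmp_path / "cohort.tsv"
        write_cohort_tsv(c, path)
        with pytest.raises(ValueError, match="row 3"):
            read_cohort_tsv(path)
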