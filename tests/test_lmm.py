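"""Mixed-model tests: Z-scoring, kinship, GLS oracle, scan, post-hoc."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import stats

from swbtwin import SimulationParams, simulate_cohort
from swbtwin.lmm import (BONFERRONI_ALPHA, KinshipEigen, association_scan,
                         build_kinship, fit_kinship_lmm, posthoc_battery,
                         swb_by_volume_strata, test_fixed_term,
                         two_group_anova_from_summary, zscore)


class TestZscore:
    def test_simple_example(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st_h.lists(st_h.floats(-1e4, 1e4), min_size=3, max_size=50)
           .filter(lambda v: len(set(v)) > 1))
    def test_mean_zero_sd_one_and_round_trip(self, values):
        x = np.asarray(values)
        z = zscore(x)
        assert abs(z.mean()) < 1e-8
        assert abs(z.std(ddof=1) - 1) < 1e-8
        np.testing.assert_allclose(z * x.std(ddof=1) + x.mean(), x,
                                   rtol=1e-9, atol=1e-6)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            zscore([2.0, 2.0, 2.0])


class TestKinship:
    @staticmethod
    def _frame(roles):
        return pd.DataFrame({
            "person_id": [f"p{i}" for i in range(len(roles))],
            "family_id": ["f1"] * len(roles),
            "zygosity_role": roles,
        })

    def test_mz_pair(self):
        k = build_kinship(self._frame(["MZ1", "MZ2"]))
        np.testing.assert_allclose(k, [[1, 1], [1, 1]])

    def test_singleton(self):
        np.testing.assert_allclose(build_kinship(self._frame(["SIB"])),
                                   [[1.0]])

    def test_dz_pair_plus_sib(self):
        k = build_kinship(self._frame(["DZ1", "DZ2", "SIB"]))
        expect = np.full((3, 3), 0.5)
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(k, expect)

    def test_duplicate_person_rejected(self):
        df = self._frame(["DZ1", "DZ2"])
        df.loc[1, "person_id"] = "p0"
        with pytest.raises(ValueError, match="duplicated"):
            build_kinship(df)

    def test_cohort_kinship_is_psd_and_symmetric(self, small_cohort):
        k = build_kinship(small_cohort)
        assert np.allclose(k, k.T)
        assert set(np.unique(k)) <= {0.0, 0.5, 1.0}
        assert np.linalg.eigvalsh(k).min() > -1e-10


class TestKinshipLmm:
    def test_beta_matches_gls_closed_form(self, rng):
        n = 150
        k = np.kron(np.eye(n // 2), np.array([[1, 0.5], [0.5, 1]]))
        x = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = x @ [1.0, 0.5, -0.2] + np.linalg.cholesky(
            0.6 * k + 0.4 * np.eye(n)) @ rng.standard_normal(n)
        fit = fit_kinship_lmm(y, x, k)
        v = fit.sigma2_g * k + fit.sigma2_e * np.eye(n)
        vi = np.linalg.inv(v)
        oracle = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-8)

    def test_identity_kinship_reduces_to_ols(self, rng):
        n = 80
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ [2.0, 1.0] + rng.standard_normal(n)
        fit = fit_kinship_lmm(y, x, np.eye(n))
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-8)
        resid = y - x @ ols
        np.testing.assert_allclose(fit.sigma2_g + fit.sigma2_e,
                                   (resid ** 2).mean(), rtol=1e-6)

    def test_component_recovery_twin_structure(self):
        rng = np.random.default_rng(4)
        blocks = [np.array([[1, 1.0], [1.0, 1]])] * 500 + \
                 [np.array([[1, 0.5], [0.5, 1]])] * 500
        from scipy.linalg import block_diag
        k = block_diag(*blocks)
        n = k.shape[0]
        y = np.linalg.cholesky(0.6 * k + 0.4 * np.eye(n) + 1e-9 * np.eye(n)) \
            @ rng.standard_normal(n)
        fit = fit_kinship_lmm(y, np.ones((n, 1)), k)
        # ~3 sampling SEs at 1000 pairs
        assert abs(fit.sigma2_g - 0.6) < 0.12
        assert abs(fit.sigma2_e - 0.4) < 0.08

    def test_rank_deficient_design_names_aliased_column(self, rng):
        n = 50
        x1 = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), x1, 2 * x1])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_kinship_lmm(rng.standard_normal(n), x, np.eye(n),
                            term_names=["i", "a", "b"])

    def test_f_equals_squared_wald_and_matches_classical_anova(self, rng):
        # balanced two-group design with K = I: F == one-way ANOVA F
        n = 60
        g = np.repeat([0.0, 1.0], n // 2)
        y = 0.4 * g + rng.standard_normal(n)
        x = np.column_stack([np.ones(n), g])
        fit = fit_kinship_lmm(y, x, np.eye(n), term_names=["i", "g"])
        f, df, p = test_fixed_term(fit, "g")
        assert f == pytest.approx((fit.beta[1] / fit.se[1]) ** 2)
        f_anova, _ = stats.f_oneway(y[g == 0], y[g == 1])
        # ML residual variance divides by n where classical uses n-2
        assert f * (n - 2) / n == pytest.approx(f_anova, rel=1e-9)
        assert df == pytest.approx(n - 2)

    def test_loglik_is_local_maximum_over_components(self, rng):
        n = 100
        k = np.kron(np.eye(n // 2), np.array([[1, 1.0], [1.0, 1]]))
        x = np.ones((n, 1))
        y = np.linalg.cholesky(0.5 * k + 0.5 * np.eye(n) + 1e-9 * np.eye(n)) \
            @ rng.standard_normal(n)
        fit = fit_kinship_lmm(y, x, k)

        def loglik(sg, se):
            v = sg * k + se * np.eye(n)
            sign, logdet = np.linalg.slogdet(v)
            vi = np.linalg.inv(v)
            b = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
            r = y - x @ b
            return -0.5 * (n * np.log(2 * np.pi) + logdet + r @ vi @ r)

        best = loglik(fit.sigma2_g, fit.sigma2_e)
        for eps in (0.9, 1.1):
            assert loglik(max(fit.sigma2_g, 1e-6) * eps,
                          fit.sigma2_e) <= best + 1e-6
            assert loglik(fit.sigma2_g,
                          fit.sigma2_e * eps) <= best + 1e-6

    def test_unknown_term_errors(self, rng):
        fit = fit_kinship_lmm(rng.standard_normal(20), np.ones((20, 1)),
                              np.eye(20), term_names=["i"])
        with pytest.raises(KeyError):
            test_fixed_term(fit, "nope")


class TestAssociationScan:
    def test_full_scan_emits_14_rows_with_bonferroni_alpha(self,
                                                           default_cohort):
        scan = association_scan(default_cohort)
        assert len(scan) == 14
        assert np.allclose(scan["alpha"], 0.05 / 14)
        assert BONFERRONI_ALPHA == pytest.approx(0.0036, abs=1e-4)

    def test_planted_hippocampal_signal_detected_null_regions_quiet(self):
        # decouple the other regions from SWB and from the hippocampus
        any_hip, both_hip, false_pos = 0, 0, 0
        n_sims = 8
        for s in range(n_sims):
            c = simulate_cohort(SimulationParams(
                seed=100 + s, genetic_common=0.0, icv_volume_fraction=0.0,
                rg_swb_vol=0.0, re_swb_vol=0.0))
            scan = association_scan(c)
            hip = scan[scan["region"] == "hippocampus"]
            other = scan[scan["region"] != "hippocampus"]
            any_hip += int(hip["linear_significant"].any())
            both_hip += int(hip["linear_significant"].all())
            false_pos += int(other["linear_significant"].sum()
                             + other["quadratic_significant"].sum())
        assert any_hip == n_sims          # signal always detected
        assert both_hip >= n_sims // 2    # usually bilaterally
        # 24 null term-tests per sim at alpha 0.0036 -> ~0.7 expected total
        assert false_pos <= 4

    def test_flags_invariant_to_row_order(self, default_cohort):
        scan1 = association_scan(default_cohort, regions=["hippocampus",
                                                          "amygdala"])
        shuffled = default_cohort.sample(frac=1.0, random_state=1)
        scan2 = association_scan(shuffled, regions=["hippocampus",
                                                    "amygdala"])
        for col in ("linear_significant", "quadratic_significant"):
            assert scan1[col].tolist() == scan2[col].tolist()
        np.testing.assert_allclose(scan1["linear_est"], scan2["linear_est"],
                                   atol=1e-6)

    def test_missing_covariate_errors(self, default_cohort):
        broken = default_cohort.drop(columns=["icv"])
        with pytest.raises(ValueError, match="icv"):
            association_scan(broken, regions=["hippocampus"])


class TestPosthoc:
    def test_unknown_variant_errors(self, default_cohort):
        with pytest.raises(ValueError, match="unknown variant"):
            posthoc_battery(default_cohort, variant="bogus")

    def test_drop_quadratic_under_linear_truth(self):
        c = simulate_cohort(SimulationParams(seed=31, quad_beta=0.0))
        from swbtwin.lmm import _EigCache, _fit_region
        cache = _EigCache(c)
        full, _ = _fit_region(c, cache, "hippocampus", "L")
        dropped = posthoc_battery(c, variant="drop_quadratic")
        est_full = full.beta[full.term_index("volume_linear")]
        est_drop = dropped[dropped["hemisphere"] == "L"]["linear_est"].iloc[0]
        # correctly specified submodel: same linear effect up to noise
        assert est_drop == pytest.approx(est_full, abs=0.1)

    def test_raw_volumes_is_a_reparameterization(self, default_cohort):
        std = posthoc_battery(default_cohort, variant="add_age_swb")
        raw = posthoc_battery(default_cohort, variant="raw_volumes")
        base = association_scan(default_cohort, regions=["hippocampus"])
        for hemi in ("L", "R"):
            b = base[base["hemisphere"] == hemi].iloc[0]
            r = raw[raw["hemisphere"] == hemi].iloc[0]
            # top-order term test is invariant under the affine rescaling
            assert r["quadratic_F"] == pytest.approx(b["quadratic_F"],
                                                     rel=1e-6)
            assert r["quadratic_est"] != pytest.approx(b["quadratic_est"])

    def test_study_interactions_layout(self, default_cohort):
        inter = posthoc_battery(default_cohort, variant="study_interactions")
        omni = inter[inter["test"].str.endswith("omnibus")]
        assert len(omni) == 4  # linear/quadratic x L/R
        assert (omni["df_num"] == 4).all()
        assert np.allclose(omni["alpha"], 0.0125)
        contrasts = inter[inter["test"].str.startswith("contrast_")]
        # contrasts are against reference study 5: studies 1..4 only
        assert set(contrasts["test"].str.extract(r"study_(\d)")[0]) == \
            {"1", "2", "3", "4"}
        assert (contrasts["alpha"] == 0.05).all()

    def test_symptom_covariate_attenuates_volume_term(self, default_cohort):
        base = association_scan(default_cohort, regions=["hippocampus"])
        adj = posthoc_battery(default_cohort, variant="add_symptom_score")
        f_base = base[base["hemisphere"] == "L"]["linear_F"].iloc[0]
        f_adj = adj[adj["hemisphere"] == "L"]["linear_F"].iloc[0]
        assert f_adj < f_base


class TestStrata:
    def test_empty_stratum_flagged(self):
        # identical L and R patterns whose Z-scores all land in (-0.5, 0.5)
        # after averaging cannot occur with ddof=1 scaling of 2 points, so
        # use a crafted frame with an explicit near-constant tail
        vals = np.array([10.0, 10.1, 10.05, 10.02, 9.98, 30.0])
        df = pd.DataFrame({"volume_hippocampus_L": vals,
                           "volume_hippocampus_R": vals,
                           "swb": np.linspace(20, 30, len(vals))})
        out = swb_by_volume_strata(df).set_index("stratum")
        assert out["n"].sum() == len(df)
        assert out.loc["low", "n"] == 0 and bool(out.loc["low", "undefined"])
        assert np.isnan(out.loc["low", "mean"])

    def test_closed_outer_cutoffs_and_ordering(self, default_cohort):
        out = swb_by_volume_strata(default_cohort)
        assert out["n"].sum() == len(default_cohort)
        low, mid, high = out.set_index("stratum").loc[
            ["low", "medium", "high"], "mean"]
        assert low < mid <= high + 0.2


class TestSummaryAnova:
    def test_printed_group_comparison(self):
        f, df, p = two_group_anova_from_summary(23, 21.5, 4.7, 35, 27.2, 2.2)
        assert f == pytest.approx(38.8, abs=0.05)
        assert df == 56
        assert p < 0.001

    def test_equal_means_give_zero(self):
        f, df, _ = two_group_anova_from_summary(10, 5.0, 1.0, 12, 5.0, 2.0)
        assert f == 0.0

    def test_matches_raw_data_t_squared(self, rng):
        # reconstruct groups with exactly the summary moments
        n1, n2 = 14, 19
        a = zscore(rng.standard_normal(n1)) * 2.5 + 10.0
        b = zscore(rng.standard_normal(n2)) * 1.5 + 11.2
        f, df, p = two_group_anova_from_summary(
            n1, a.mean(), a.std(ddof=1), n2, b.mean(), b.std(ddof=1))
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-9)
        assert p == pytest.approx(p_t, rel=1e-9)

    def test_bad_sd_errors(self):
        with pytest.raises(ValueError, match="positive"):
            two_group_anova_from_summary(5, 1.0, 0.0, 5, 2.0, 1.0)
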