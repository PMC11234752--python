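import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ibspec.stats import (
    bonferroni,
    bootstrap_ci,
    choose_and_run_test,
    correlation_matrix_bootstrap,
    embed_spectra,
    pca_spectra,
    posthoc,
    t_test,
    wilcoxon_signed_rank,
)
from ibspec.synthetic import make_band_spectrum


class TestDecisionTree:
    def test_gaussian_groups_select_anova(self):
        rng = np.random.default_rng(0)
        picks = [
            choose_and_run_test([rng.normal(size=50) for _ in range(3)]).chosen_test
            for _ in range(100)
        ]
        assert picks.count("ANOVA") >= 90

    def test_exponential_groups_select_kruskal(self):
        rng = np.random.default_rng(1)
        picks = [
            choose_and_run_test(
                [rng.exponential(size=50) for _ in range(3)]
            ).chosen_test
            for _ in range(100)
        ]
        assert picks.count("Kruskal-Wallis") >= 90

    def test_null_type_i_error_calibrated(self):
        """Full pipeline (pretests -> omnibus) rejects ~5% of Gaussian nulls."""
        rng = np.random.default_rng(2)
        n_rep = 1500
        rejections = sum(
            choose_and_run_test([rng.normal(size=50) for _ in range(3)]).p < 0.05
            for _ in range(n_rep)
        )
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_report_records_decision_path(self):
        rng = np.random.default_rng(3)
        rep = choose_and_run_test(
            [rng.normal(size=30) for _ in range(3)], posthoc_method="tukey"
        )
        assert len(rep.normality_p) == 3
        assert 0 <= rep.homoscedasticity_p <= 1
        assert rep.pretest_threshold == pytest.approx(0.05 / 4)
        assert rep.posthoc_table is not None and len(rep.posthoc_table) == 3
        d = rep.to_dict()
        assert d["chosen_test"] in ("ANOVA", "Kruskal-Wallis")

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n="):
            choose_and_run_test([np.ones(2), np.zeros(5)])


class TestPosthoc:
    def test_tukey_two_groups_reduces_to_pooled_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        p_tukey = posthoc([a, b], "tukey")["p"].iloc[0]
        _, p_t = t_test(a, b)
        assert p_tukey == pytest.approx(p_t, abs=1e-6)

    def test_dunnett_two_groups_matches_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1, 20)
        p_d = posthoc([a, b], "dunnett", control_index=0)["p"].iloc[0]
        _, p_t = t_test(a, b)
        assert p_d == pytest.approx(p_t, rel=0.02)

    def test_dunnett_requires_control(self):
        with pytest.raises(ValueError, match="control"):
            posthoc([np.zeros(5), np.ones(5)], "dunnett")

    def test_equal_means_rarely_flagged(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100)          :
            groups = [rng.normal(size=20) for _ in range(3)]
            hits += (posthoc(groups, "tukey")["p"].min() < 0.05)
        assert hits <= 10

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
        table = posthoc(groups, "tukey")
        shifted = table[(table.group_j == 2)]
        assert (shifted["p"] < 0.001).all()

    def test_dunn_follows_kruskal_branch(self):
        rng = np.random.default_rng(8)
        rep = choose_and_run_test(
            [rng.exponential(size=40) for _ in range(3)], posthoc_method="tukey"
        )
        assert rep.chosen_test == "Kruskal-Wallis"
        assert rep.posthoc_method == "dunn"


class TestBonferroni:
    def test_uncapped_adjustment(self):
        np.testing.assert_allclose(bonferroni([0.05], m=4), [0.2])
        np.testing.assert_allclose(bonferroni([0.55], m=4), [2.2])

    def test_identity_for_single_comparison(self):
        np.testing.assert_allclose(bonferroni([0.3], m=1), [0.3])

    def test_cap_mode(self):
        np.testing.assert_allclose(bonferroni([0.55], m=4, cap=True), [1.0])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)

    def test_adjustment_count_recorded_no_silent_double_correction(self):
        rng = np.random.default_rng(9)
        rep = choose_and_run_test([rng.normal(size=20) for _ in range(3)], m=5)
        assert rep.n_adjustments == 1
        assert rep.p_adj == pytest.approx(5 * rep.p)


class TestBootstrapCI:
    def test_constant_data_degenerate_interval(self):
        lo, hi = bootstrap_ci(np.full(10, 3.3), seed=0)
        assert lo == hi == 3.3

    def test_seed_determinism(self):
        v = np.random.default_rng(10).normal(size=40)
        assert bootstrap_ci(v, seed=7) == bootstrap_ci(v, seed=7)
        assert bootstrap_ci(v, seed=7) != bootstrap_ci(v, seed=8)

    def test_coverage_sanity_small(self):
        rng = np.random.default_rng(11)
        cover = sum(
            (lambda lo_hi: lo_hi[0] <= 0 <= lo_hi[1])(
                bootstrap_ci(rng.normal(size=100), n_boot=999, rng=rng)
            )
            for _ in range(60)
        )
        assert cover >= 50

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0])


class TestCorrelationMatrix:
    @staticmethod
    def _tables(rng, n_tables=20, n=50, rho=0.0, k=4):
        tables = []
        for _ in range(n_tables):
            x = rng.normal(size=(n, k))
            if rho:
                x[:, 1] = rho * x[:, 0] + np.sqrt(1 - rho**2) * x[:, 1]
            tables.append(pd.DataFrame(x, columns=[f"p{i}" for i in range(k)]))
        return tables

    def test_duplicated_property_flagged_with_r_one(self):
        rng = np.random.default_rng(12)
        tables = self._tables(rng)
        for t in tables:
            t["dup"] = t["p0"]
        res = correlation_matrix_bootstrap(tables, n_boot=999, seed=0)
        assert res.r_mean.loc["p0", "dup"] == pytest.approx(1.0)
        assert res.significant.loc["p0", "dup"]

    def test_planted_correlation_detected(self):
        rng = np.random.default_rng(13)
        tables = self._tables(rng, rho=0.8)
        res = correlation_matrix_bootstrap(tables, n_boot=1999, seed=0)
        assert res.significant.loc["p0", "p1"]
        assert 0.7 <= res.r_mean.loc["p0", "p1"] <= 0.9

    def test_constant_property_excluded_not_crashing(self):
        rng = np.random.default_rng(14)
        tables = self._tables(rng, n_tables=3)
        for t in tables:
            t["const"] = 1.0
        res = correlation_matrix_bootstrap(tables, n_boot=499, seed=0)
        assert np.isnan(res.r_mean.loc["p0", "const"])
        assert res.n_datasets.loc["p0", "const"] == 0

    def test_bonferroni_factor_is_pair_count(self):
        rng = np.random.default_rng(15)
        res = correlation_matrix_bootstrap(self._tables(rng, k=5), n_boot=199, seed=0)
        assert res.m == 10


class TestPCAAndEmbedding:
    def _spectra(self, n=12, seed=16):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            s = make_band_spectrum(
                [(1654.0, 12.0, 1.0), (1628.0, 10.0, 0.2 + 0.6 * rng.random())],
                noise_sd=0.005,
                rng=rng,
            )
            out.append(s)
        return out

    def test_pc1_loading_extremal_in_beta_band(self):
        """Spectra differing only in the 1628 band: PC1 weight concentrates
        there (the component tracking beta-sheet content)."""
        spectra = self._spectra()
        res = pca_spectra(spectra)
        grid = spectra[0].grid.values
        peak_wn = grid[np.argmax(np.abs(res.components[0]))]
        assert 1620 <= peak_wn <= 1640

    def test_sign_convention_deterministic(self):
        res = pca_spectra(self._spectra())
        for comp in res.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_reconstruction_residual_monotone_in_components(self):
        spectra = self._spectra(n=10)
        x = np.vstack([s.ir_amplitude for s in spectra])
        res = pca_spectra(x, n_components=5)
        resids = []
        for k in range(1, 6):
            recon = res.mean + res.scores[:, :k] @ res.components[:k]
            resids.append(np.linalg.norm(x - recon))
        assert all(b <= a + 1e-12 for a, b in zip(resids, resids[1:]))

    def test_fewer_than_three_spectra_rejected(self):
        with pytest.raises(ValueError):
            pca_spectra(np.zeros((2, 10)))

    def test_embedding_via_pca_and_callable(self):
        x = np.random.default_rng(17).normal(size=(20, 50))
        out = embed_spectra(x, method="pca")
        assert out.shape == (20, 2)
        out2 = embed_spectra(x, method=lambda m: m[:, :2])
        assert out2.shape == (20, 2)
        with pytest.raises(ValueError):
            embed_spectra(x, method="nope")


def test_paired_utility_tests_detect_positive_shift():
    rng = np.random.default_rng(18)
    a = rng.normal(0.5, 1.0, 40)
    b = a - rng.normal(0.5, 0.3, 40)
    _, p_w = wilcoxon_signed_rank(a, b)
    _, p_t = t_test(a, b, paired=True)
    assert p_w < 0.001 and p_t < 0.001
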