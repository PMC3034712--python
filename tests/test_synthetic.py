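"""Generator correctness: error model structure, metadata, and fixtures."""

import numpy as np
import pytest

from recallval import (
    ErrorModelSpec,
    correct_relative_risk,
    category_means,
    expected_kappa,
    kappa_agreement,
    load_config,
    load_paired_table,
    make_cohort_fixture,
    ordinal_association,
    pearson_with_se,
    rdr_point,
    simulate_binary,
    simulate_ordinal,
    simulate_quantitative,
    simulate_ratio_pair,
)


class TestQuantitative:
    def test_no_error_limit(self):
        spec = ErrorModelSpec(n=500, seed=1)
        s = simulate_quantitative(spec)
        assert np.array_equal(s.self_report, s.reference)

    @pytest.mark.parametrize(
        "b, sigma_eps, lam", [(1.0, 0.5, 0.8), (0.8, 0.0, 1.25), (1.0, 1.0, 0.5)]
    )
    def test_attenuation_metadata(self, b, sigma_eps, lam):
        spec = ErrorModelSpec(b=b, sigma_eps=sigma_eps, n=10, seed=0)
        assert spec.attenuation == pytest.approx(lam)
        s = simulate_quantitative(spec)
        assert s.provenance["attenuation"] == pytest.approx(lam)

    def test_pure_function_of_seed(self):
        spec = ErrorModelSpec(sigma_eps=0.3, n=100, seed=9)
        a = simulate_quantitative(spec)
        b = simulate_quantitative(spec)
        assert np.array_equal(a.self_report, b.self_report)
        assert np.array_equal(a.reference, b.reference)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ErrorModelSpec(sigma_eps=-1)
        with pytest.raises(ValueError):
            ErrorModelSpec(b=0)
        with pytest.raises(ValueError):
            ErrorModelSpec(rho_eps=1.5)

    @pytest.mark.parametrize("lam_target", [0.5, 0.8, 1.0, 1.25])
    def test_full_pipeline_parameter_recovery(self, lam_target):
        # invert lambda = b*sigma_T^2/(b^2 sigma_T^2 + sigma_eps^2)
        if lam_target <= 1.0:
            b, sigma_eps = 1.0, np.sqrt(1 / lam_target - 1)
        else:
            b, sigma_eps = 1 / lam_target, 0.0
        spec = ErrorModelSpec(b=b, sigma_eps=sigma_eps, n=50_000, seed=1234)
        assert spec.attenuation == pytest.approx(lam_target)
        s = simulate_quantitative(spec)
        assert rdr_point(category_means(s)) == pytest.approx(lam_target, abs=0.05)
        r, _ = pearson_with_se(s.self_report, s.reference)
        analytic_r = b * 1.0 / np.sqrt(b**2 + sigma_eps**2)
        assert r == pytest.approx(analytic_r, abs=0.02)

    def test_rr_correction_recovers_generative_coefficient(self, rng):
        # outcome log-risk beta*T; regressing it on the self-report gives
        # beta*lambda, and RDR correction restores beta
        beta = 0.4
        spec = ErrorModelSpec(sigma_eps=0.5, n=50_000, seed=77)
        s = simulate_quantitative(spec)
        T = s.reference  # sigma_u = 0, so the reference is the truth
        log_risk = beta * T + rng.normal(0, 0.2, s.n)
        x = s.self_report
        beta_naive = np.cov(x, log_risk, bias=True)[0, 1] / np.var(x)
        lam = s.provenance["attenuation"]
        assert beta_naive / beta == pytest.approx(lam, abs=0.03)
        rdr = rdr_point(category_means(s))
        corrected = np.log(correct_relative_risk(np.exp(beta_naive), rdr))
        assert corrected == pytest.approx(beta, abs=0.03)


class TestRatioPair:
    def test_independent_errors(self):
        spec = ErrorModelSpec(mu_T=100, sigma_T=8, sigma_eps=3, n=20_000, seed=3)
        _, _, ratio = simulate_ratio_pair(spec, spec, rho_eps=0.0)
        en = ratio.provenance["error_numerator"]
        ed = ratio.provenance["error_denominator"]
        assert abs(np.corrcoef(en, ed)[0, 1]) < 0.03

    def test_configured_error_correlation(self):
        # waist/hip-style components with correlated reporting errors
        waist = ErrorModelSpec(mu_T=80, sigma_T=8, sigma_eps=4, n=20_000, seed=6)
        hip = ErrorModelSpec(mu_T=100, sigma_T=8, sigma_eps=4, n=20_000, seed=6)
        _, _, ratio = simulate_ratio_pair(waist, hip, rho_eps=0.55)
        en = ratio.provenance["error_numerator"]
        ed = ratio.provenance["error_denominator"]
        assert np.corrcoef(en, ed)[0, 1] == pytest.approx(0.55, abs=0.03)

    def test_correlated_errors_partially_cancel(self):
        # perfectly correlated equal-variance errors leave the ratio less
        # noisy than independent errors would
        base = dict(mu_T=100, sigma_T=5, sigma_eps=5, n=20_000)
        spec = ErrorModelSpec(seed=8, **base)
        _, _, ratio_corr = simulate_ratio_pair(spec, spec, rho_eps=1.0, seed=8)
        _, _, ratio_ind = simulate_ratio_pair(spec, spec, rho_eps=0.0, seed=8)
        r_corr, _ = pearson_with_se(ratio_corr.self_report, ratio_corr.reference)
        r_ind, _ = pearson_with_se(ratio_ind.self_report, ratio_ind.reference)
        assert r_corr > r_ind

    def test_nonpositive_denominator_resampled(self):
        spec_num = ErrorModelSpec(mu_T=1, sigma_T=0.1, n=2000, seed=2)
        spec_den = ErrorModelSpec(mu_T=0.5, sigma_T=0.5, n=2000, seed=2)
        with pytest.warns(UserWarning, match="resampled"):
            _, den, ratio = simulate_ratio_pair(spec_num, spec_den, rho_eps=0.0)
        assert (den.reference > 0).all() and (den.self_report > 0).all()
        assert ratio.provenance["n_redrawn"] > 0


class TestOrdinal:
    def test_noise_free_levels_ordered_by_truth(self):
        spec = ErrorModelSpec(n=300, seed=4)
        s = simulate_ordinal(spec, thresholds=[-0.43, 0.43])
        order = np.argsort(s.reference)
        assert np.all(np.diff(s.self_report[order]) >= 0)

    def test_spearman_shrinks_with_noise(self):
        rhos = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            spec = ErrorModelSpec(sigma_eps=sigma, n=4000, seed=15)
            s = simulate_ordinal(spec, thresholds=[-0.5, 0.0, 0.5])
            rhos.append(ordinal_association(s).spearman_r)
        assert np.all(np.diff(rhos) < 0)

    def test_single_threshold_feeds_kappa(self):
        spec = ErrorModelSpec(sigma_eps=0.2, n=1000, seed=5)
        s = simulate_ordinal(spec, thresholds=[0.0])
        ref_binary = (s.reference > 0).astype(int)
        res = kappa_agreement(s.self_report, ref_binary)
        assert 0.5 < res.kappa <= 1.0


class TestBinary:
    def test_perfect_reporting(self):
        s = simulate_binary(0.5, 1.0, 1.0, n=500, seed=1)
        assert np.array_equal(s.self_report, s.reference)
        assert s.provenance["expected_kappa"] == pytest.approx(1.0)

    def test_coin_flip_reporting_chance_kappa(self):
        assert expected_kappa(0.3, 0.5, 0.5) == pytest.approx(0.0)

    def test_empirical_matches_closed_form(self):
        s = simulate_binary(0.7, 0.95, 0.9, n=50_000, seed=2024)
        expected = s.provenance["expected_kappa"]
        empirical = kappa_agreement(s.self_report, s.reference).kappa
        assert empirical == pytest.approx(expected, abs=0.02)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            simulate_binary(1.3, 0.9, 0.9, n=10)


class TestCohortFixture:
    CONFIG = {
        "height": {"mu_T": 163, "sigma_T": 6, "sigma_eps": 2},
        "weight": {"mu_T": 65, "sigma_T": 10, "sigma_eps": 3, "b": 0.95},
    }

    def test_row_count(self, tmp_path):
        path = tmp_path / "cohort.csv"
        table = make_cohort_fixture(self.CONFIG, path, seed=1, n_participants=100)
        assert len(table) == 200
        assert path.read_text().count("\n") == 201  # header + 200 rows

    def test_missingness_rate(self, tmp_path):
        config = {
            "height": {"mu_T": 163, "sigma_T": 6, "missing_rate": 0.1},
        }
        table = make_cohort_fixture(
            config, tmp_path / "c.csv", seed=7, n_participants=2000
        )
        n_missing = table["self_report"].isna().sum()
        # binomial(2000, 0.1): 4 sd tolerance
        assert abs(n_missing - 200) < 4 * np.sqrt(2000 * 0.1 * 0.9)

    def test_subgroup_dependent_missingness(self, tmp_path):
        config = {
            "height": {
                "mu_T": 163,
                "sigma_T": 6,
                "missing_rate_by_subgroup": {"manual": 0.3, "non-manual": 0.05},
            }
        }
        table = make_cohort_fixture(
            config, tmp_path / "c.csv", seed=7, n_participants=2000
        )
        by = table.groupby("social_class")["self_report"].apply(
            lambda s: s.isna().mean()
        )
        assert by["manual"] > by["non-manual"]

    def test_byte_identical_for_fixed_seed(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        make_cohort_fixture(self.CONFIG, p1, seed=42, n_participants=50)
        make_cohort_fixture(self.CONFIG, p2, seed=42, n_participants=50)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fixture_loads_through_data_model(self, tmp_path):
        path = tmp_path / "cohort.csv"
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            "height:\n  kind: quantitative\nweight:\n  kind: quantitative\n"
        )
        make_cohort_fixture(self.CONFIG, path, seed=3, n_participants=80)
        samples = load_paired_table(path, load_config(cfg_path))
        assert samples["height"].n == 80
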