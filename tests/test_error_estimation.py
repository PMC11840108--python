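import numpy as np
import pytest

from bwasbias import (
    ResamplingConfig,
    estimate_false_negative_rate,
    estimate_false_positive_rate,
    estimate_inflation_rate,
    estimate_power,
    estimate_prob_replication,
    estimate_sign_error_rate,
    log_spaced_sizes,
    resample_subjects,
    resample_summary_effect,
    resample_summary_effects,
    run_resampling_sweep,
)
from bwasbias.error_estimation import prob_replication_from_tables

from conftest import make_table


class TestResampleSubjects:
    def test_rows_stay_paired(self, small_sample):
        rng = np.random.default_rng(0)
        idx = rng.integers(0, small_sample.n_subjects, size=20)
        rng_again = np.random.default_rng(0)
        resampled = resample_subjects(small_sample, 20, rng_again)
        assert np.array_equal(resampled.edges, small_sample.edges[idx])
        assert np.array_equal(resampled.behaviour, small_sample.behaviour[idx])

    def test_minimal_size_and_determinism(self, small_sample):
        a = resample_subjects(small_sample, 4, seed=5)
        b = resample_subjects(small_sample, 4, seed=5)
        assert a.edges.shape == (4, small_sample.n_edges)
        assert np.array_equal(a.edges, b.edges)

    def test_bootstrap_inclusion_fraction(self, small_sample):
        # at size = n, a with-replacement draw contains on average a fraction
        # 1 - (1 - 1/n)^n of distinct subjects
        n = small_sample.n_subjects
        fractions = [
            len(np.unique(
                np.random.default_rng(seed).integers(0, n, size=n)
            )) / n
            for seed in range(200)
        ]
        expected = 1 - (1 - 1 / n) ** n
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert np.mean(fractions) == pytest.approx(expected, abs=3 * se)
        # and the implementation draws uniformly with replacement, matching
        resampled = resample_subjects(small_sample, n, seed=0)
        distinct = len(np.unique(resampled.edges[:, 0]))
        assert 0.5 * n < distinct < n

    def test_size_bounds_enforced(self, small_sample):
        with pytest.raises(ValueError):
            resample_subjects(small_sample, 3)
        with pytest.raises(ValueError):
            resample_subjects(small_sample, small_sample.n_subjects + 1)


class TestResampleSummaryEffects:
    @pytest.mark.parametrize("size", [25, 100, 1000])
    def test_fisher_scale_spread(self, size):
        rng = np.random.default_rng(size)
        draws = resample_summary_effects(np.zeros(100_000), size, rng)
        sd = np.arctanh(draws).std()
        assert sd == pytest.approx(1 / np.sqrt(size - 3), rel=0.01)

    def test_centred_on_r_star(self):
        rng = np.random.default_rng(3)
        draws = resample_summary_effects(np.full(50_000, 0.11), 1000, rng)
        z = np.arctanh(draws)
        assert z.mean() == pytest.approx(np.arctanh(0.11),
                                         abs=3 * z.std() / np.sqrt(len(z)))
        assert z.var() == pytest.approx(1 / 997, rel=0.05)

    def test_scalar_wrapper_and_validation(self):
        value = resample_summary_effect(0.5, 100, seed=1)
        assert -1 < value < 1
        with pytest.raises(ValueError):
            resample_summary_effect(1.0, 100)
        with pytest.raises(ValueError):
            resample_summary_effects(np.array([0.2]), 3)


class TestEstimatorsOnHandBuiltTables:
    """Counting checks against the enumerated 8-effect pair (see conftest)."""

    def test_false_negative_rate(self, eight_effect_tables):
        full, rep = eight_effect_tables
        assert estimate_false_negative_rate(full, rep, 0.05) == pytest.approx(2 / 6)

    def test_power_is_complement(self, eight_effect_tables):
        full, rep = eight_effect_tables
        assert estimate_power(full, rep, 0.05) == pytest.approx(4 / 6)

    def test_sign_error_rate(self, eight_effect_tables):
        full, rep = eight_effect_tables
        assert estimate_sign_error_rate(full, rep, 0.05) == pytest.approx(2 / 6)

    def test_false_positive_rate(self, eight_effect_tables):
        full, rep = eight_effect_tables
        assert estimate_false_positive_rate(full, rep, 0.05) == pytest.approx(1 / 2)

    @pytest.mark.parametrize("magnitude,expected", [(0.0, 2 / 3), (0.5, 1 / 3)])
    def test_inflation_rate(self, eight_effect_tables, magnitude, expected):
        full, rep = eight_effect_tables
        assert estimate_inflation_rate(full, rep, 0.05, magnitude) == (
            pytest.approx(expected)
        )

    @pytest.mark.parametrize("require_sign,expected", [(True, 3 / 6), (False, 4 / 6)])
    def test_prob_replication_from_tables(self, eight_effect_tables,
                                          require_sign, expected):
        full, rep = eight_effect_tables
        assert prob_replication_from_tables(full, rep, 0.05, require_sign) == (
            pytest.approx(expected)
        )

    def test_six_effect_counting_case(self):
        # 3 significant in full, 1 of those significant again -> FNR 2/3
        full = make_table([0.5, 0.4, -0.6, 0.05, 0.01, -0.02], n=100)
        rep = make_table([0.5, 0.1, -0.02, 0.05, 0.01, -0.02], n=100,
                         label="resample")
        assert estimate_false_negative_rate(full, rep, 0.05) == pytest.approx(2 / 3)


class TestEstimatorEdgeCases:
    def test_self_replication(self, eight_effect_tables):
        full, _ = eight_effect_tables
        assert estimate_false_negative_rate(full, full, 0.05) == 0.0
        assert estimate_power(full, full, 0.05) == 1.0
        assert estimate_sign_error_rate(full, full, 0.05) == 0.0
        assert estimate_false_positive_rate(full, full, 0.05) == 0.0
        for magnitude in (0.0, 0.2, 1.0):
            # strict inequality: identical magnitudes are never inflated
            assert estimate_inflation_rate(full, full, 0.05, magnitude) == 0.0
        assert prob_replication_from_tables(full, full, 0.05) == 1.0

    def test_empty_denominators_are_missing(self):
        full = make_table([0.01, -0.02, 0.03], n=100)
        rep = make_table([0.5, 0.6, 0.7], n=100, label="resample")
        assert np.isnan(estimate_false_negative_rate(full, rep, 0.05))
        assert np.isnan(estimate_power(full, rep, 0.05))
        assert np.isnan(estimate_sign_error_rate(full, rep, 0.05))
        assert np.isnan(estimate_inflation_rate(full, rep, 0.05, 0.0))
        # every full-sample effect significant -> FPR denominator empty
        all_sig = make_table([0.5, 0.6, 0.7], n=100)
        assert np.isnan(estimate_false_positive_rate(all_sig, rep, 0.05))

    def test_zero_correlation_counts_as_sign_mismatch(self):
        full = make_table([0.5, 0.5], n=100)
        rep = make_table([0.0, 0.5], n=100, label="resample")
        assert estimate_sign_error_rate(full, rep, 0.05) == pytest.approx(0.5)

    def test_length_mismatch_rejected(self, eight_effect_tables):
        full, _ = eight_effect_tables
        other = make_table([0.1, 0.2], n=100)
        with pytest.raises(ValueError, match="different effects"):
            estimate_power(full, other, 0.05)

    def test_estimates_bounded(self, small_sample):
        # randomised property: every estimator lies in [0, 1] or is missing
        rng = np.random.default_rng(0)
        for _ in range(20):
            r_full = rng.uniform(-0.6, 0.6, 30)
            r_rep = rng.uniform(-0.6, 0.6, 30)
            full = make_table(r_full, n=50)
            rep = make_table(r_rep, n=50, label="resample")
            alpha = rng.choice([0.3, 0.05, 0.01])
            for value in (
                estimate_false_negative_rate(full, rep, alpha),
                estimate_power(full, rep, alpha),
                estimate_sign_error_rate(full, rep, alpha),
                estimate_false_positive_rate(full, rep, alpha),
                estimate_inflation_rate(full, rep, alpha, 0.2),
            ):
                assert np.isnan(value) or 0.0 <= value <= 1.0


class TestProbReplication:
    def test_runs_on_subject_sample(self, small_sample):
        value = estimate_prob_replication(small_sample, 40, 0.3, seed=1)
        assert np.isnan(value) or 0.0 <= value <= 1.0

    def test_disjoint_mode_bounds(self, small_sample):
        with pytest.raises(ValueError, match="disjoint"):
            estimate_prob_replication(small_sample, 60, 0.05, seed=1,
                                      mode="disjoint")
        value = estimate_prob_replication(small_sample, 40, 0.3, seed=1,
                                          mode="disjoint")
        assert np.isnan(value) or 0.0 <= value <= 1.0


@pytest.fixture(scope="module")
def sweep(small_sample):
    config = ResamplingConfig(
        sizes=(20, 40, 80), n_iterations=10, alphas=(0.2, 0.05),
        inflation_magnitudes=(0.0, 0.5), seed=7,
    )
    return run_resampling_sweep(small_sample, config), config


class TestResamplingSweep:

    def test_complete_grid(self, sweep):
        frame, config = sweep
        non_inflation = frame[frame["estimator"] != "inflation_rate"]
        assert len(non_inflation) == len(config.sizes) * len(config.alphas) * 5
        inflation = frame[frame["estimator"] == "inflation_rate"]
        assert len(inflation) == (
            len(config.sizes) * len(config.alphas) * len(config.inflation_magnitudes)
        )

    def test_determinism(self, small_sample, sweep):
        frame, config = sweep
        again = run_resampling_sweep(small_sample, config)
        assert frame.equals(again)

    def test_power_complementarity_recordwise(self, sweep):
        frame, _ = sweep
        pivot = frame[frame["estimator"].isin(["power", "false_negative_rate"])]
        pivot = pivot.pivot_table(index=["size", "alpha"], columns="estimator",
                                  values="value", dropna=False)
        both = pivot.dropna()
        assert np.allclose(both["power"] + both["false_negative_rate"], 1.0)

    def test_values_bounded_or_missing(self, sweep):
        frame, _ = sweep
        values = frame["value"].to_numpy()
        finite = np.isfinite(values)
        assert np.all((values[finite] >= 0) & (values[finite] <= 1))

    def test_strict_alpha_yields_missing_not_zero(self, small_sample):
        config = ResamplingConfig(sizes=(40,), n_iterations=3,
                                  alphas=(0.05, 1e-7), seed=1)
        frame = run_resampling_sweep(small_sample, config)
        strict = frame[(frame["alpha"] == 1e-7)
                       & (frame["estimator"] == "power")]
        # 45 null effects essentially never cross 1e-7 in the full sample
        assert strict["n_eligible"].iloc[0] == 0
        assert np.isnan(strict["value"].iloc[0])


class TestResamplingConfig:
    def test_log_spaced_default(self):
        sizes = log_spaced_sizes()
        assert sizes[0] == 25 and sizes[-1] == 1000
        assert len(sizes) == 10
        assert list(sizes) == sorted(set(sizes))

    def test_validation(self):
        with pytest.raises(ValueError):
            ResamplingConfig(sizes=(3,))
        with pytest.raises(ValueError):
            ResamplingConfig(alphas=(0.01, 0.05))
        with pytest.raises(ValueError):
            ResamplingConfig(prob_replication_mode="bogus")
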