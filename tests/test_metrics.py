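"""Analysis metrics: identities, closed forms, and estimator recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasticv1.metrics import (
    DEFAULT_ORIENTATIONS,
    UndefinedMetric,
    correlation_vs_similarity,
    discriminability,
    mean_pairwise_correlation,
    mutual_information_per_spike,
    orientation_bandwidth,
    orientation_diversity_index,
    population_sparseness,
    receptive_field_maps,
    reconstruction_error,
    rf_from_weights,
    rf_similarity,
    spike_triggered_average,
)


class TestReceptiveFields:
    def test_pure_on_weights(self, rng):
        w = np.zeros((288, 2))
        on = rng.uniform(0, 1, 144)
        w[:144, 0] = on
        assert np.allclose(rf_from_weights(w, 0).map.ravel(), on)

    def test_equal_on_off_cancels(self, rng):
        w = np.zeros((288, 1))
        w[:144, 0] = w[144:, 0] = rng.uniform(0, 1, 144)
        assert np.all(rf_from_weights(w, 0).map == 0)

    def test_gabor_fixture_roundtrip(self, gabor_population):
        w = np.stack([fx.on_off_weights() for fx in gabor_population], axis=1)
        maps = receptive_field_maps(w)
        for j, fx in enumerate(gabor_population):
            np.testing.assert_allclose(maps[j], fx.map, atol=1e-12)


class TestSta:
    def test_single_spike_returns_that_stimulus(self, rng):
        stimuli = rng.normal(size=(5, 12, 12))
        counts = np.array([0, 0, 1, 0, 0])
        np.testing.assert_array_equal(
            spike_triggered_average(stimuli, counts), stimuli[2]
        )

    def test_stimulus_independent_spiking_recovers_mean(self, rng):
        stimuli = rng.normal(loc=3.0, size=(20_000, 4))
        counts = rng.poisson(2.0, size=20_000)
        sta = spike_triggered_average(stimuli, counts)
        np.testing.assert_allclose(sta, stimuli.mean(axis=0), atol=0.1)

    def test_zero_spikes_undefined(self, rng):
        with pytest.raises(UndefinedMetric):
            spike_triggered_average(rng.normal(size=(5, 2)), np.zeros(5))


class TestSimilarity:
    def test_identity_negation_orthogonality(self, rng):
        v = rng.normal(size=(12, 12))
        assert rf_similarity(v, v) == pytest.approx(1.0)
        assert rf_similarity(v, -v) == pytest.approx(-1.0)
        w = rng.normal(size=(12, 12))
        w -= v * np.sum(v * w) / np.sum(v * v)
        assert rf_similarity(v, w) == pytest.approx(0.0, abs=1e-12)

    def test_zero_vector_undefined(self):
        with pytest.raises(UndefinedMetric):
            rf_similarity(np.zeros(4), np.ones(4))


class TestOrientationBandwidth:
    def test_triangular_curve_closed_form(self):
        orientations = np.arange(0.0, 180.0, 8.0)
        peak = 88.0
        response = np.maximum(0.0, 1.0 - np.abs(orientations - peak) / 45.0)
        obw = orientation_bandwidth(response, orientations)
        assert obw == pytest.approx(45.0 * (1 - 1 / np.sqrt(2)), abs=1e-9)

    def test_gaussian_curve_closed_form(self):
        orientations = np.arange(0.0, 180.0, 8.0)
        sigma = 20.0
        response = np.exp(-((orientations - 88.0) ** 2) / (2 * sigma**2))
        obw = orientation_bandwidth(response, orientations)
        assert obw == pytest.approx(sigma * np.sqrt(np.log(2)), rel=0.02)

    def test_flat_curve_undefined(self):
        with pytest.raises(UndefinedMetric):
            orientation_bandwidth(np.ones(23), DEFAULT_ORIENTATIONS)

    def test_wraparound_peak_at_edge(self):
        # 9° grid divides the 180° domain evenly, so the wrap gap is
        # uniform; peak at 0° forces the left flank through the wrap
        orientations = np.arange(0.0, 180.0, 9.0)
        response = np.exp(-((np.minimum(orientations, 180 - orientations)) ** 2) / (2 * 20.0**2))
        obw = orientation_bandwidth(response, orientations)
        assert obw == pytest.approx(20.0 * np.sqrt(np.log(2)), rel=0.05)


class TestCircularVariance:
    def test_flat_curve_is_one(self):
        from plasticv1.metrics import circular_variance

        # a 9° grid tiles the doubled-angle circle exactly, so the flat
        # curve's resultant vector vanishes
        assert circular_variance(
            np.ones(20), np.arange(0.0, 180.0, 9.0)
        ) == pytest.approx(1.0)

    def test_delta_curve_is_zero(self):
        from plasticv1.metrics import circular_variance

        r = np.zeros(23)
        r[7] = 5.0
        assert circular_variance(r) == pytest.approx(0.0)

    def test_sharper_gaussian_has_lower_value(self):
        from plasticv1.metrics import circular_variance

        orientations = np.arange(0.0, 180.0, 8.0)
        narrow = np.exp(-((orientations - 88.0) ** 2) / (2 * 10.0**2))
        broad = np.exp(-((orientations - 88.0) ** 2) / (2 * 40.0**2))
        assert circular_variance(narrow) < circular_variance(broad)

    def test_zero_response_undefined(self):
        from plasticv1.metrics import UndefinedMetric, circular_variance

        with pytest.raises(UndefinedMetric):
            circular_variance(np.zeros(23))


class TestOdi:
    def test_uniform_histogram_gives_one(self):
        preferred = np.repeat(np.arange(0, 180, 8), 3)
        assert orientation_diversity_index(preferred) == pytest.approx(1.0)

    def test_single_bin_gives_one_over_k(self):
        preferred = np.full(50, 12.0)
        assert orientation_diversity_index(preferred, n_bins=23) == pytest.approx(1 / 23)

    def test_three_bin_hand_oracle(self):
        # P = (0.5, 0.25, 0.25) against uniform Q over 3 bins:
        # ODI = exp(-KL) = (9/8)^(-1/2)
        preferred = np.array([10.0, 20.0, 70.0, 130.0])
        odi = orientation_diversity_index(preferred, n_bins=3)
        assert odi == pytest.approx(1.0 / np.sqrt(1.125), abs=1e-12)

    def test_empty_undefined(self):
        with pytest.raises(UndefinedMetric):
            orientation_diversity_index(np.array([]))

    @given(st.permutations(list(range(6))))
    @settings(max_examples=20, deadline=None)
    def test_bin_order_invariance(self, perm):
        """ODI depends on the histogram multiset, not on bin positions."""
        counts = np.array([8, 4, 2, 1, 1, 0])
        base = np.repeat(np.arange(6) * 30.0 + 5.0, counts)
        shuffled = np.repeat(np.arange(6) * 30.0 + 5.0, counts[list(perm)])
        assert orientation_diversity_index(base, n_bins=6) == pytest.approx(
            orientation_diversity_index(shuffled, n_bins=6)
        )


class TestSparseness:
    @pytest.mark.parametrize(
        "responses, expected",
        [
            (np.array([5.0, 0, 0, 0]), 1.0),
            (np.array([3.0, 3.0, 3.0, 3.0]), 0.0),
            (np.array([1.0, 1.0, 0.0, 0.0]), 2.0 / 3.0),
        ],
    )
    def test_identities(self, responses, expected):
        assert population_sparseness(responses) == pytest.approx(expected)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedMetric):
            population_sparseness(np.zeros(5))

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(1e-3, 100.0)),
            min_size=2, max_size=50,
        ).filter(lambda r: sum(r) > 0)
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_in_unit_interval(self, responses):
        s = population_sparseness(np.asarray(responses))
        assert -1e-9 <= s <= 1.0 + 1e-9


class TestReconstructionError:
    def test_perfect_reconstruction_is_zero(self, rng):
        img = rng.normal(size=(24, 24))
        assert reconstruction_error(img, img) == 0.0

    def test_offset_and_scale_invariance(self, rng):
        img = rng.normal(size=(24, 24))
        assert reconstruction_error(img, 3.0 * img + 7.0) == pytest.approx(0.0, abs=1e-12)


class TestMutualInformation:
    def test_noiseless_binary_code_two_bits_per_spike(self):
        counts = np.array([[0] * 100, [1] * 100])  # 2 stimuli x 100 reps
        assert mutual_information_per_spike(counts) == pytest.approx(2.0)

    def test_uninformative_code_zero(self):
        counts = np.full((5, 100), 3)
        assert mutual_information_per_spike(counts) == pytest.approx(0.0)

    def test_noiseless_code_equals_total_entropy(self, rng):
        # responses identical across repetitions: I = H(r)
        per_stim = rng.integers(1, 6, size=10)
        counts = np.tile(per_stim[:, None], (1, 100))
        vals, freq = np.unique(per_stim, return_counts=True)
        p = freq / freq.sum()
        h = -np.sum(p * np.log2(p))
        expected = h / per_stim.mean()
        assert mutual_information_per_spike(counts) == pytest.approx(expected)

    def test_zero_spikes_undefined(self):
        with pytest.raises(UndefinedMetric):
            mutual_information_per_spike(np.zeros((3, 10)))


class TestDiscriminability:
    def test_identical_distributions_give_zero(self, rng):
        a = rng.normal(size=(100, 8))
        assert discriminability(a, a) == 0.0

    def test_symmetric_under_condition_swap(self, rng):
        # the projection axis flips together with the labels, so the
        # printed statistic is symmetric and nonnegative in expectation
        a = rng.normal(0.0, 1.0, size=(100, 4))
        b = rng.normal(0.5, 1.0, size=(100, 4))
        assert discriminability(a, b) == pytest.approx(discriminability(b, a))

    def test_matches_closed_form_for_gaussian_clouds(self):
        rng = np.random.default_rng(8)
        mu_a, mu_b, sd = 0.0, 2.0, 1.0
        a = rng.normal(mu_a, sd, size=(4000, 1))
        b = rng.normal(mu_b, sd, size=(4000, 1))
        # projection onto the mean difference scales the mean separation
        # by |mu_a - mu_b| and the variances by its square
        d = abs(mu_a - mu_b)
        expected = d * d / ((sd * d) ** 2)
        assert discriminability(a, b) == pytest.approx(expected, rel=0.1)


class TestCorrelationStructure:
    def test_duplicated_neuron_fully_correlated(self, rng):
        base = rng.poisson(5.0, size=40).astype(float)
        responses = np.stack([base, base, rng.poisson(5.0, size=40)])
        rfs = rng.normal(size=(3, 12, 12))
        rfs[1] = rfs[0]  # identical RFs -> top similarity bin
        out = correlation_vs_similarity(responses, rfs)
        assert out["bin_mean_correlation"][-1] == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        a = np.array([1.0, 2, 3, 4, 5])
        responses = np.stack([a, -a + 6.0])
        rfs = np.random.default_rng(0).normal(size=(2, 4))
        out = correlation_vs_similarity(responses, rfs)
        assert out["mean_correlation"] == pytest.approx(-1.0)

    def test_independent_rates_mean_correlation_vanishes(self, rng):
        responses = rng.poisson(5.0, size=(10, 4000)).astype(float)
        rfs = rng.normal(size=(10, 4))
        out = correlation_vs_similarity(responses, rfs)
        assert abs(out["mean_correlation"]) < 0.05

    def test_constant_neuron_excluded_and_counted(self, rng):
        responses = rng.poisson(4.0, size=(3, 30)).astype(float)
        responses[1] = 2.0
        out = correlation_vs_similarity(responses, rng.normal(size=(3, 4)))
        assert out["n_neurons_excluded"] == 1

    def test_mean_pairwise_correlation_perfect_pair(self):
        counts = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        mean, excluded = mean_pairwise_correlation(counts)
        assert mean == pytest.approx(1.0)
        assert excluded == 0
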