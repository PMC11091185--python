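"""Category probabilities, the threshold-shift equivalence, and likelihoods."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erspcm.pcm import (
    ext_pcm_category_probs,
    pcm_category_probs,
    response_loglik,
    shifted_thresholds,
)
from erspcm.scale import RatingScaleSpec, ers_scoring_weights

from conftest import brute_force_probs

finite_floats = st.floats(-3, 3, allow_nan=False)


class TestPCMProbs:
    def test_zero_thresholds_give_uniform(self):
        p = pcm_category_probs(0.0, np.zeros(8))
        assert np.allclose(p, 1 / 9, atol=1e-14)

    def test_binary_symmetry(self):
        assert np.allclose(pcm_category_probs(0.0, np.zeros(1)), [0.5, 0.5])

    def test_matches_brute_force_oracle(self, rng):
        """Direct-summation oracle agreement, including the worked K=3 case."""
        p = pcm_category_probs(0.0, np.array([-1.0, 1.0]))
        assert np.allclose(np.round(p, 4), [0.2119, 0.5761, 0.2119])
        for _ in range(50):
            K = rng.integers(2, 10)
            theta = rng.normal()
            tau = rng.normal(size=K - 1)
            assert np.allclose(
                pcm_category_probs(theta, tau),
                brute_force_probs(theta, tau),
                atol=1e-10,
            )

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            pcm_category_probs(np.nan, np.zeros(3))
        with pytest.raises(ValueError):
            pcm_category_probs(0.0, np.array([np.inf, 0.0]))


class TestExtPCMProbs:
    def test_reduces_to_pcm_at_zero_ers(self, rng):
        s = ers_scoring_weights(9)
        tau = rng.normal(size=8)
        assert np.allclose(
            ext_pcm_category_probs(0.7, 0.0, tau, s),
            pcm_category_probs(0.7, tau),
            atol=1e-14,
        )

    def test_worked_three_category_example(self):
        # unnormalized terms (2, 1, 2) at eta = ln 2
        p = ext_pcm_category_probs(0.0, np.log(2), np.zeros(2), np.array([1.0, 0.0, 1.0]))
        assert np.allclose(p, [0.4, 0.2, 0.4], atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            K = int(rng.integers(3, 10))
            s = ers_scoring_weights(K)
            theta, eta = rng.normal(size=2)
            tau = rng.normal(size=K - 1)
            assert np.allclose(
                ext_pcm_category_probs(theta, eta, tau, s),
                brute_force_probs(theta, tau, eta, s),
                atol=1e-10,
            )

    def test_palindromic_for_symmetric_thresholds(self, rng):
        """Antisymmetric tau at theta=0 gives P(k) = P(K+1-k) for any eta."""
        s = ers_scoring_weights(9)
        half = rng.normal(size=4)
        tau = np.concatenate([half, -half[::-1]])
        for eta in (-1.3, 0.4, 2.0):
            p = ext_pcm_category_probs(0.0, eta, tau, s)
            assert np.allclose(p, p[::-1], atol=1e-12)

    def test_weight_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            ext_pcm_category_probs(0.0, 0.5, np.zeros(8), np.ones(5))


class TestThresholdShiftEquivalence:
    def test_identity_at_zero(self, rng):
        s = ers_scoring_weights(9)
        tau = rng.normal(size=8)
        assert np.allclose(shifted_thresholds(tau, 0.0, s), tau)

    def test_unit_shift_pattern_on_k9(self):
        out = shifted_thresholds(np.zeros(8), 1.0, ers_scoring_weights(9))
        assert np.allclose(out, [1, 1, 1, 1, -1, -1, -1, -1])

    def test_parameterizations_agree_on_random_draws(self, rng):
        """Scoring-weight and threshold-shift forms agree to 1e-12."""
        max_dev = 0.0
        for _ in range(1000):
            K = int(rng.integers(3, 12))
            s = ers_scoring_weights(K)
            theta, eta = rng.normal(size=2) * 2
            tau = rng.normal(size=K - 1) * 2
            a = ext_pcm_category_probs(theta, eta, tau, s)
            b = pcm_category_probs(theta, shifted_thresholds(tau, eta, s))
            max_dev = max(max_dev, float(np.abs(a - b).max()))
        assert max_dev < 1e-12


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    theta=finite_floats,
    eta=finite_floats,
    data=st.data(),
)
def test_probability_invariants(theta, eta, data):
    """Normalization, positivity, stochastic ordering in theta, ERS monotonicity."""
    K = data.draw(st.integers(3, 9))
    tau = np.array(data.draw(st.lists(finite_floats, min_size=K - 1, max_size=K - 1)))
    s = ers_scoring_weights(K)
    p = ext_pcm_category_probs(theta, eta, tau, s)
    assert abs(p.sum() - 1) < 1e-12
    assert np.all(p > 0)
    # expected category strictly increases in theta
    k = np.arange(1, K + 1)
    lo = ext_pcm_category_probs(theta - 0.5, eta, tau, s)
    assert (p * k).sum() > (lo * k).sum()


def test_ers_monotonicity_at_scale_center(rng):
    """At theta=0 with symmetric tau, extreme-category mass rises with eta."""
    s = ers_scoring_weights(9)
    half = rng.normal(size=4)
    tau = np.concatenate([half, -half[::-1]])
    etas = np.linspace(-2, 2, 9)
    mass = [
        ext_pcm_category_probs(0.0, e, tau, s)[[0, -1]].sum() for e in etas
    ]
    assert np.all(np.diff(mass) > 0)


def test_numerical_stability_at_extreme_parameters():
    s = ers_scoring_weights(9)
    for theta, eta in [(30, 30), (-30, 30), (30, -30), (-30, -30), (0, 30)]:
        tau = np.array([30.0, -30, 30, -30, 30, -30, 30, -30])
        p = ext_pcm_category_probs(float(theta), float(eta), tau, s)
        assert np.all(np.isfinite(p))
        assert abs(p.sum() - 1) < 1e-12


class TestResponseLoglik:
    def test_single_uniform_cell(self):
        scale = RatingScaleSpec(9)
        ll = response_loglik(
            np.array([[4]]), np.array([0.0]), np.zeros((1, 8)), scale
        )
        assert np.isclose(ll, np.log(1 / 9))

    def test_all_missing_is_zero(self):
        scale = RatingScaleSpec(9)
        ll = response_loglik(
            np.zeros((3, 2), dtype=int), np.zeros(3), np.zeros((2, 8)), scale
        )
        assert ll == 0.0

    def test_toy_set_matches_cellwise_oracle(self, rng):
        """2 persons x 2 items: sum of four individually computed log-probs."""
        scale = RatingScaleSpec(5)
        tau = rng.normal(size=(2, 4))
        theta = rng.normal(size=2)
        y = rng.integers(1, 6, size=(2, 2))
        expected = sum(
            np.log(brute_force_probs(theta[p], tau[i])[y[p, i] - 1])
            for p in range(2)
            for i in range(2)
        )
        got = response_loglik(y, theta, tau, scale)
        assert np.isclose(got, expected, atol=1e-10)

    def test_ext_variant_matches_cellwise_oracle(self, rng):
        scale = RatingScaleSpec(5)
        tau = rng.normal(size=(2, 4))
        theta, eta = rng.normal(size=(2, 2))
        y = rng.integers(1, 6, size=(2, 2))
        expected = sum(
            np.log(brute_force_probs(theta[p], tau[i], eta[p], scale.s)[y[p, i] - 1])
            for p in range(2)
            for i in range(2)
        )
        got = response_loglik(y, theta, tau, scale, eta=eta, variant="ext_pcm")
        assert np.isclose(got, expected, atol=1e-10)

    def test_out_of_range_cell_is_named(self):
        scale = RatingScaleSpec(5)
        y = np.array([[2, 6], [1, 3]])
        with pytest.raises(ValueError, match="person index 0, item index 1"):
            response_loglik(y, np.zeros(2), np.zeros((2, 4)), scale)

    def test_variant_contract(self):
        scale = RatingScaleSpec(5)
        y = np.ones((1, 1), dtype=int)
        with pytest.raises(ValueError, match="eta"):
            response_loglik(y, np.zeros(1), np.zeros((1, 4)), scale, variant="ext_pcm")
        with pytest.raises(ValueError, match="eta"):
            response_loglik(
                y, np.zeros(1), np.zeros((1, 4)), scale, eta=np.zeros(1), variant="pcm"
            )
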