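import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_partial_transfer_entropy, brute_transfer_entropy
from cvte.entropy import (
    TEConfig,
    cte,
    cte_components,
    cte_direct_magphase,
    hte,
    joint_pmf,
    partial_transfer_entropy,
    scte,
    ste,
    transfer_entropy,
)
from cvte.signals import ComplexSeries
from cvte.simulate import generate_pair
from cvte.symbolic import bin_raw, symbolize


class TestJointPMF:
    def test_degenerate_single_cell(self):
        pmf = joint_pmf([[0, 0, 0], [1, 1, 1]])
        assert pmf.probabilities[0, 1] == 1.0
        assert pmf.counts.sum() == pmf.total == 3

    def test_hand_counted_example(self):
        pmf = joint_pmf([[0, 1, 0, 1], [0, 1, 1, 0]])
        np.testing.assert_allclose(pmf.probabilities,
                                   [[0.25, 0.25], [0.25, 0.25]])

    def test_normalization_and_marginal_consistency(self, rng):
        a = rng.integers(0, 4, 60)
        b = rng.integers(0, 4, 60)
        c = rng.integers(0, 4, 60)
        tri = joint_pmf([a, b, c], dims=["a", "b", "c"])
        assert tri.probabilities.sum() == pytest.approx(1.0)
        # marginalizing the trivariate table reproduces the bivariate one
        bi = joint_pmf([a, b], dims=["a", "b"])
        np.testing.assert_array_equal(tri.marginal(["a", "b"]).counts, bi.counts)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_pmf([[0, 1], [0, 1, 2]])


class TestTransferEntropy:
    def test_constant_target_is_zero(self, rng):
        src = rng.integers(0, 4, 50)
        assert transfer_entropy(src, np.ones(50, int), tau=1) == 0.0

    def test_deterministic_alternation_zero(self):
        # the target's own past fully determines its present
        source = [0, 1, 0, 1, 0, 1, 0, 1]
        target = [1, 0, 1, 0, 1, 0, 1, 0]
        val = transfer_entropy(source, target, tau=1, unit="nats")
        assert val == pytest.approx(brute_transfer_entropy(source, target, 1),
                                    abs=1e-12)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_iid_streams_near_zero(self):
        rng = np.random.default_rng(5)
        s = rng.integers(0, 4, 10_000)
        t = rng.integers(0, 4, 10_000)
        assert transfer_entropy(s, t, tau=1, unit="bits") < 0.01

    def test_unit_conversion(self, rng):
        s = rng.integers(0, 4, 40)
        t = rng.integers(0, 4, 40)
        nats = transfer_entropy(s, t, 1, unit="nats")
        bits = transfer_entropy(s, t, 1, unit="bits")
        assert bits == pytest.approx(nats / np.log(2))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            transfer_entropy([0, 1, 0], [1, 0, 1], tau=2)


class TestPartialTransferEntropy:
    def test_conditioner_equal_source_is_zero(self, rng):
        s = rng.integers(0, 4, 60)
        t = rng.integers(0, 4, 60)
        assert partial_transfer_entropy(s, t, s, tau=1) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_constant_target_is_zero(self, rng):
        s = rng.integers(0, 4, 60)
        c = rng.integers(0, 4, 60)
        assert partial_transfer_entropy(s, np.zeros(60, int), c, 1) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_constant_conditioner_reduces_to_te(self, rng):
        s = rng.integers(0, 4, 80)
        t = rng.integers(0, 4, 80)
        c = np.ones(80, int)
        assert partial_transfer_entropy(s, t, c, 2, unit="nats") == pytest.approx(
            transfer_entropy(s, t, 2, unit="nats"), abs=1e-12
        )

    def test_small_triple_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        s = rng.integers(0, 3, 12)
        t = rng.integers(0, 3, 12)
        c = rng.integers(0, 3, 12)
        val = partial_transfer_entropy(s, t, c, tau=1, unit="nats")
        assert val == pytest.approx(
            brute_partial_transfer_entropy(s, t, c, 1), abs=1e-12
        )


@given(st.integers(0, 2**31 - 1), st.integers(4, 12), st.integers(1, 2))
@settings(max_examples=100, deadline=None)
def test_te_nonnegative_and_oracle_equal(seed, T, tau):
    """Plug-in TE equals the enumeration oracle and is non-negative."""
    if T <= tau + 2:
        T = tau + 3
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 4, T)
    t = rng.integers(0, 4, T)
    val = transfer_entropy(s, t, tau, unit="nats")
    assert val >= -1e-12
    assert val == pytest.approx(brute_transfer_entropy(s, t, tau), abs=1e-10)


@given(st.integers(0, 2**31 - 1), st.integers(4, 12))
@settings(max_examples=100, deadline=None)
def test_pte_nonnegative_and_oracle_equal(seed, T):
    """Plug-in partial TE equals the enumeration oracle and is non-negative."""
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 4, T)
    t = rng.integers(0, 4, T)
    c = rng.integers(0, 4, T)
    val = partial_transfer_entropy(s, t, c, 1, unit="nats")
    assert val >= -1e-12
    assert val == pytest.approx(
        brute_partial_transfer_entropy(s, t, c, 1), abs=1e-10
    )


class TestComplexEstimators:
    def test_constant_target_all_zero(self, rng):
        z1 = ComplexSeries(np.abs(rng.standard_normal(60)),
                           rng.standard_normal(60))
        z2 = ComplexSeries(np.full(60, 2.0), np.full(60, 0.5))
        cfg = TEConfig(tau=1)
        assert cte(z1, z2, cfg) == pytest.approx(0.0, abs=1e-12)
        assert scte(z1, z2, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_additive_decomposition(self):
        pair = generate_pair("N1", seed=11)
        z1, z2 = pair.observed()
        cfg = TEConfig(tau=1)
        comps = cte_components(z1, z2, cfg)
        assert cte(z1, z2, cfg) == pytest.approx(sum(comps.values()), abs=1e-10)
        assert scte(z1, z2, cfg) == pytest.approx(
            comps["mag_mag"] + comps["phase_phase"], abs=1e-10
        )
        # cte - scte equals the two partial cross terms
        assert cte(z1, z2, cfg) - scte(z1, z2, cfg) == pytest.approx(
            comps["mag_mag_given_phase"] + comps["phase_phase_given_mag"],
            abs=1e-10,
        )

    def test_cte_terms_match_componentwise_oracle(self):
        """Each of the four terms equals its brute-force counterpart."""
        pair = generate_pair("N1", seed=3)
        z1, z2 = pair.observed()
        cfg = TEConfig(tau=1, unit="nats")
        comps = cte_components(z1, z2, cfg)
        a = symbolize(z1.magnitude).codes
        th = symbolize(z1.phase).codes
        b = symbolize(z2.magnitude).codes
        ph = symbolize(z2.phase).codes
        assert comps["mag_mag"] == pytest.approx(
            brute_transfer_entropy(a, b, 1), abs=1e-10)
        assert comps["phase_phase"] == pytest.approx(
            brute_transfer_entropy(th, ph, 1), abs=1e-10)
        assert comps["mag_mag_given_phase"] == pytest.approx(
            brute_partial_transfer_entropy(a, b, th, 1), abs=1e-10)
        assert comps["phase_phase_given_mag"] == pytest.approx(
            brute_partial_transfer_entropy(th, ph, a, 1), abs=1e-10)

    def test_scte_phase_noise_close_to_magnitude_te(self):
        """With causality-free random phases the phase term sits at the
        finite-sample floor, so sCTE is close to the magnitude-only TE."""
        pair = generate_pair("L3", T=1000, seed=4)
        z1, z2 = pair.observed()
        cfg = TEConfig(tau=1)
        phase_term = scte(z1, z2, cfg) - ste(z1, z2, cfg)
        assert 0.0 <= phase_term < 0.05

    def test_ste_is_te_of_symbolized_magnitudes(self, l1_pair):
        z1, z2 = l1_pair.observed()
        cfg = TEConfig(tau=1, unit="nats")
        expected = brute_transfer_entropy(
            symbolize(z1.magnitude).codes, symbolize(z2.magnitude).codes, 1
        )
        assert ste(z1, z2, cfg) == pytest.approx(expected, abs=1e-10)

    def test_hte_matches_bruteforce_on_binned_toy(self, rng):
        m1 = rng.standard_normal(8)
        m2 = rng.standard_normal(8)
        z1 = ComplexSeries(m1, np.zeros(8))
        z2 = ComplexSeries(m2, np.zeros(8))
        expected = brute_transfer_entropy(bin_raw(m1, m2), bin_raw(m2, m1), 1)
        assert hte(z1, z2, TEConfig(tau=1, unit="nats")) == pytest.approx(
            expected, abs=1e-10
        )

    def test_cte_direct_cross_terms_are_plain_te(self):
        pair = generate_pair("L1", seed=9)
        z1, z2 = pair.observed()
        cfg = TEConfig(tau=1, unit="nats")
        a = symbolize(z1.magnitude).codes
        th = symbolize(z1.phase).codes
        b = symbolize(z2.magnitude).codes
        ph = symbolize(z2.phase).codes
        expected = (
            brute_transfer_entropy(a, b, 1)
            + brute_transfer_entropy(th, ph, 1)
            + brute_transfer_entropy(b, th, 1)
            + brute_transfer_entropy(a, ph, 1)
        )
        assert cte_direct_magphase(z1, z2, cfg) == pytest.approx(expected,
                                                                 abs=1e-10)

    def test_positive_scaling_invariance_of_symbolic_estimators(self):
        pair = generate_pair("L1", seed=2)
        z1, z2 = pair.observed()
        z1s = ComplexSeries(7.5 * z1.magnitude, 0.3 * z1.phase)
        cfg = TEConfig(tau=1)
        assert cte(z1, z2, cfg) == pytest.approx(cte(z1s, z2, cfg), abs=1e-12)

    def test_literal_weighting_mode_differs(self):
        pair = generate_pair("N1", seed=6)
        z1, z2 = pair.observed()
        std = cte(z1, z2, TEConfig(tau=1))
        lit = cte(z1, z2, TEConfig(tau=1, literal_eq=True))
        assert std != pytest.approx(lit)
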