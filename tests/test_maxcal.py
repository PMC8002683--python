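import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maxcalbench.fsp import build_state_space, stationary_distribution
from maxcalbench.maxcal import (
    MaxCalParamsSGAA,
    MaxCalParamsTS,
    ModeError,
    find_two_modes,
    maxcal_effective_rates,
    path_distribution_sgaa,
    path_distribution_ts,
    transition_matrix_sgaa,
    transition_matrix_ts,
)
from tests.oracles import (
    enum_path_probs_sgaa,
    enum_path_probs_ts,
    enum_transition_sgaa,
    enum_transition_ts,
)

multipliers = st.floats(-1.5, 1.5)


class TestPathDistributionSGAA:
    def test_uniform_exponent_case(self):
        """All multipliers zero, NA=3, M=1: Q = 2*2^3 and every
        probability is C(3, l_A)/16."""
        d = path_distribution_sgaa(3, MaxCalParamsSGAA(0.0, 0.0, 0.0, 1))
        assert d.Q == pytest.approx(16.0)
        from math import comb
        for la in range(2):
            for lA in range(4):
                assert d.probs[la, lA] == pytest.approx(comb(3, lA) / 16.0)

    def test_empty_survival_limit(self):
        """NA=0 forces l_A=0 and the distribution over l_alpha is a
        truncated geometric in exp(h_alpha)."""
        p = MaxCalParamsSGAA(0.7, -0.3, 0.2, 3)
        d = path_distribution_sgaa(0, p)
        assert d.probs.shape == (4, 1)
        w = np.exp(p.h_alpha * np.arange(4))
        assert np.abs(d.probs[:, 0] - w / w.sum()).max() < 1e-12

    def test_matches_enumeration(self):
        p = MaxCalParamsSGAA(0.5, -0.2, 0.1, 1)
        d = path_distribution_sgaa(2, p)
        ref, Q = enum_path_probs_sgaa(2, 0.5, -0.2, 0.1, 1)
        assert d.Q == pytest.approx(Q, rel=1e-12)
        for (la, lA), prob in ref.items():
            assert d.probs[la, lA] == pytest.approx(prob, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(multipliers, multipliers, multipliers, st.integers(0, 8),
           st.integers(1, 4))
    def test_normalized_for_random_multipliers(self, ha, hA, KA, NA, M):
        d = path_distribution_sgaa(NA, MaxCalParamsSGAA(ha, hA, KA, M))
        assert abs(d.probs.sum() - 1.0) < 1e-12
        assert (d.probs >= 0).all()

    def test_mean_production_monotone_in_h_alpha(self):
        """Raising h_alpha strictly increases the conditional mean
        production; the coupling K_A amplifies it more at larger NA."""
        means = [path_distribution_sgaa(5, MaxCalParamsSGAA(h, 0.5, 0.1, 4)).mean("l_alpha")
                 for h in (-1.0, 0.0, 1.0)]
        assert means[0] < means[1] < means[2]
        gain_small = (
            path_distribution_sgaa(2, MaxCalParamsSGAA(-0.5, 0.5, 0.3, 4)).mean("l_alpha")
            - path_distribution_sgaa(2, MaxCalParamsSGAA(-0.5, 0.5, 0.0, 4)).mean("l_alpha"))
        gain_large = (
            path_distribution_sgaa(10, MaxCalParamsSGAA(-0.5, 0.5, 0.3, 4)).mean("l_alpha")
            - path_distribution_sgaa(10, MaxCalParamsSGAA(-0.5, 0.5, 0.0, 4)).mean("l_alpha"))
        assert gain_large > gain_small

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MaxCalParamsSGAA(0.0, 0.0, 0.0, 0)
        with pytest.raises(ValueError):
            MaxCalParamsSGAA(np.inf, 0.0, 0.0, 2)


class TestPathDistributionTS:
    def test_decoupled_factorizes(self):
        """With both couplings zero the joint distribution is the outer
        product of two single-gene distributions."""
        p = MaxCalParamsTS(0.3, -0.4, 0.0, 0.0, 2)
        d = path_distribution_ts(3, 2, p)
        da = path_distribution_sgaa(3, MaxCalParamsSGAA(0.3, -0.4, 0.0, 2))
        db = path_distribution_sgaa(2, MaxCalParamsSGAA(0.3, -0.4, 0.0, 2))
        outer = np.einsum("ab,cd->abcd", da.probs, db.probs)
        assert np.abs(d.probs - outer).max() < 1e-12

    def test_matches_enumeration(self):
        p = MaxCalParamsTS(0.4, -0.1, 0.15, -0.25, 1)
        d = path_distribution_ts(1, 1, p)
        ref, Q = enum_path_probs_ts(1, 1, 0.4, -0.1, 0.15, -0.25, 1)
        assert d.Q == pytest.approx(Q, rel=1e-12)
        for key, prob in ref.items():
            assert d.probs[key] == pytest.approx(prob, abs=1e-12)

    def test_exchange_symmetry_at_equal_counts(self):
        p = MaxCalParamsTS(0.2, 0.3, 0.1, -0.2, 2)
        d = path_distribution_ts(4, 4, p)
        assert np.abs(d.probs - d.probs.transpose(2, 3, 0, 1)).max() < 1e-12

    def test_cross_coupling_represses_production(self):
        """A strongly negative cross-coupling suppresses production of
        the second gene when the first is abundant."""
        kwargs = dict(h_alpha=0.2, h_A=0.5, K_A_alpha=0.0, M=3)
        base = path_distribution_ts(12, 0, MaxCalParamsTS(K_A_beta=0.0, **kwargs))
        coupled = path_distribution_ts(12, 0, MaxCalParamsTS(K_A_beta=-2.0, **kwargs))
        assert coupled.mean("l_beta") < base.mean("l_beta")


class TestTransitionMatrixSGAA:
    def test_from_zero_only_production_reachable(self):
        sp = build_state_space([("N", 10)])
        T = transition_matrix_sgaa(MaxCalParamsSGAA(0.2, 0.4, 0.1, 3), sp).P
        assert T[4:, 0].sum() == 0.0
        assert T[:4, 0].sum() == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(multipliers, multipliers, multipliers, st.integers(2, 6),
           st.integers(1, 3))
    def test_matches_enumeration_oracle(self, ha, hA, KA, nmax, M):
        sp = build_state_space([("N", nmax)])
        T = transition_matrix_sgaa(MaxCalParamsSGAA(ha, hA, KA, M), sp).P
        ref = enum_transition_sgaa(nmax, ha, hA, KA, M)
        assert np.abs(T - ref).max() < 1e-10

    def test_monte_carlo_sampling_oracle(self, rng):
        """Histogram of j = l_alpha + l_A over 10^6 draws from the path
        distribution at i=5 agrees with the matrix column within four
        multinomial standard errors."""
        p = MaxCalParamsSGAA(-0.4, 0.6, 0.08, 3)
        sp = build_state_space([("N", 12)])
        col = transition_matrix_sgaa(p, sp).P[:12, 5]
        d = path_distribution_sgaa(5, p)
        flat = d.probs.ravel()
        draws = rng.choice(flat.size, size=1_000_000, p=flat)
        la, lA = np.unravel_index(draws, d.probs.shape)
        hist = np.bincount(la + lA, minlength=12) / 1e6
        se = np.sqrt(np.maximum(col * (1 - col), 1e-12) / 1e6)
        assert (np.abs(hist[:12] - col) <= 4 * se + 1e-9).all()

    def test_production_suppressed_at_large_negative_h_alpha(self):
        sp = build_state_space([("N", 15)])
        T = transition_matrix_sgaa(MaxCalParamsSGAA(-30.0, 0.5, 0.0, 4), sp).P
        for i in range(15):
            assert T[i + 1:15, i].sum() < 1e-10

    def test_bistable_chain_with_positive_coupling(self):
        """With K_A > 0 and suitable multipliers the stationary law of
        the MaxCal chain is bimodal: the model can represent the switch
        it is fit to."""
        sp = build_state_space([("N", 80)])
        T = transition_matrix_sgaa(MaxCalParamsSGAA(-0.56, 0.74, 0.0295, 14), sp)
        pi = stationary_distribution(T)
        lo, hi = find_two_modes(pi)
        assert lo < 10 < 30 < hi


class TestTransitionMatrixTS:
    def test_matches_enumeration_oracle(self):
        sp = build_state_space([("NA", 4), ("NB", 4)])
        p = MaxCalParamsTS(0.3, -0.2, 0.1, -0.15, 2)
        T = transition_matrix_ts(p, sp).P
        ref = enum_transition_ts(4, 0.3, -0.2, 0.1, -0.15, 2)
        assert np.abs(T - ref).max() < 1e-10

    def test_decoupled_is_outer_product(self):
        sp2 = build_state_space([("NA", 5), ("NB", 5)])
        sp1 = build_state_space([("N", 5)])
        p = MaxCalParamsTS(0.2, 0.1, 0.0, 0.0, 2)
        p1 = MaxCalParamsSGAA(0.2, 0.1, 0.0, 2)
        T2 = transition_matrix_ts(p, sp2).P[:25, :25]
        T1 = transition_matrix_sgaa(p1, sp1).P[:5, :5]
        # the joint path weight factorizes, so the tracked block is the
        # tensor product of the single-gene tracked blocks
        outer = np.einsum("ji,lk->jlik", T1, T1).reshape(25, 25)
        assert np.abs(T2 - outer).max() < 1e-10

    def test_symmetric_params_invariant_under_exchange(self):
        sp = build_state_space([("NA", 5), ("NB", 5)])
        p = MaxCalParamsTS(0.25, -0.1, 0.12, -0.2, 2)
        T = transition_matrix_ts(p, sp).P
        perm = np.empty(sp.dimension, dtype=int)
        for idx in range(sp.n_tracked):
            i, k = sp.state(idx)
            perm[idx] = sp.index((k, i))
        perm[sp.sink_index] = sp.sink_index
        assert np.abs(T - T[np.ix_(perm, perm)]).max() < 1e-12


class TestEffectiveRates:
    def test_no_coupling_means_equal_production_everywhere(self):
        """K_A = 0 decouples production from abundance, so the
        conditional mean production is the same at every state."""
        p = MaxCalParamsSGAA(-0.5, 0.8, 0.0, 5)
        means = [path_distribution_sgaa(N, p).mean("l_alpha")
                 for N in (0, 3, 10, 25)]
        assert np.ptp(means) < 1e-12

    def test_pure_survival_degradation_rate(self):
        """With production suppressed, survivors are binomial with
        probability sigma = exp(h_A)/(1+exp(h_A)) and the implied
        degradation rate is (1-sigma)/dt at every N."""
        hA = 0.9
        sigma = np.exp(hA) / (1 + np.exp(hA))
        p = MaxCalParamsSGAA(-30.0, hA, 0.0, 3)
        dt = 300.0
        for N in (1, 4, 9):
            d = path_distribution_sgaa(N, p)
            assert d.mean("l_A") == pytest.approx(N * sigma, rel=1e-9)
            r = (N - d.mean("l_A")) / (N * dt)
            assert r == pytest.approx((1 - sigma) / dt, rel=1e-9)

    def test_extraction_on_bistable_chain(self):
        params = MaxCalParamsSGAA(-0.56, 0.74, 0.0295, 14)
        sp = build_state_space([("N", 80)])
        rates = maxcal_effective_rates(params, sp, 300.0)
        assert rates["NL"] < rates["NH"]
        assert 0 < rates["peff"] < rates["peff_star"]
        assert rates["reff"] > 0

    def test_unimodal_law_raises_mode_error(self):
        p = MaxCalParamsSGAA(-0.5, 0.2, 0.0, 3)
        sp = build_state_space([("N", 30)])
        with pytest.raises(ModeError):
            maxcal_effective_rates(p, sp, 300.0)

    def test_ts_bimodal_joint_modes(self):
        """A symmetric toggle chain with repressive cross-coupling has a
        bimodal marginal with the joint modes on opposite corners."""
        p = MaxCalParamsTS(0.1, 0.9, 0.0, -0.15, 8)
        sp = build_state_space([("NA", 25), ("NB", 25)])
        from maxcalbench.maxcal import maxcal_effective_rates_ts
        rates = maxcal_effective_rates_ts(p, sp, 300.0)
        assert rates["NL"] < rates["NH"]
        assert rates["peff"] > rates["peff_star"] > 0
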