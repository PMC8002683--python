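import numpy as np
import pytest
from scipy.optimize import minimize

from maxcalbench.cgm import CGMParamsSGAA, sgaa_cgm_network
from maxcalbench.fsp import auto_nmax, build_state_space
from maxcalbench.inference import (
    OptimizerConfig,
    count_transitions,
    initial_guesses,
    log_likelihood,
    maximize_likelihood,
    model_state_space,
    observed_transition_matrix,
    select_m,
)
from maxcalbench.maxcal import MaxCalParamsSGAA, simulate_chain_sgaa
from maxcalbench.ssa import FrameSeries, SimulationConfig, simulate_ssa

from tests.conftest import make_series


class TestCountTransitions:
    def test_constant_series(self):
        omega = count_transitions([make_series([3, 3, 3, 3])], 1)
        assert omega.n_transitions == 3
        assert omega.pairs.tolist() == [[3, 3]]
        assert omega.counts.tolist() == [3]

    def test_windowing_arithmetic(self):
        omega = count_transitions([make_series([0, 1, 2, 3, 4])], 2)
        assert dict(zip(map(tuple, omega.pairs), omega.counts)) == {
            (0, 2): 1, (2, 4): 1}

    def test_total_count_formula(self):
        """floor((n_frames - 1)/m) transitions per trajectory, additive
        over trajectories (the full-scale bookkeeping: 100 trajectories
        of 2017 frames at m=16 give 12,600 pooled transitions)."""
        trajs = [make_series(np.zeros(2017, dtype=int)) for _ in range(5)]
        omega = count_transitions(trajs, 16)
        assert omega.n_transitions == 5 * 126

    def test_permutation_invariance(self, rng):
        trajs = [make_series(rng.integers(0, 10, size=50)) for _ in range(6)]
        a = count_transitions(trajs, 3)
        b = count_transitions(trajs[::-1], 3)
        assert np.array_equal(a.pairs, b.pairs)
        assert np.array_equal(a.counts, b.counts)

    def test_mixed_delta_t_rejected(self):
        trajs = [make_series([1, 2], delta_t=300.0),
                 make_series([1, 2], delta_t=600.0)]
        with pytest.raises(ValueError, match="frame interval"):
            count_transitions(trajs, 1)

    def test_two_species_pairs(self):
        counts = np.array([[1, 5], [2, 4], [3, 3]])
        omega = count_transitions([FrameSeries(300.0, counts, ["A", "B"])], 1)
        assert omega.n_species == 2
        assert dict(zip(map(tuple, omega.pairs), omega.counts)) == {
            (1, 5, 2, 4): 1, (2, 4, 3, 3): 1}


class TestSelectM:
    def test_square_wave_returns_dwell(self):
        from maxcalbench.io import make_fixture
        (wave,) = make_fixture("square_wave")
        assert select_m([wave]) == 50

    def test_constant_series_returns_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert select_m([make_series(np.full(100, 7))]) == 1

    def test_clamped_by_trajectory_length(self):
        counts = np.array([3] * 30 + [40] * 30 + [3] * 30 + [40] * 30)
        assert select_m([make_series(counts)]) <= 12

    def test_consistent_with_threshold_crossing_estimate(self, sgaa_48h_trajectories):
        """The chosen m is within a factor of two of an independent
        dwell estimate from threshold crossings at the histogram valley."""
        trajs = sgaa_48h_trajectories
        m = select_m(trajs)
        pooled = np.concatenate([t.counts[:, 0] for t in trajs])
        thresh = 20  # valley between the two modes of the default circuit
        dwells = []
        for t in trajs:
            lab = t.counts[:, 0] > thresh
            change = np.flatnonzero(np.diff(lab.astype(int)))
            dwells += np.diff(np.concatenate([[0], change, [lab.size]])).tolist()
        independent = np.clip(np.mean(dwells), 1, t.n_frames // 10)
        assert independent / 2 <= m <= independent * 2


class TestLogLikelihood:
    def test_certain_transition_is_zero(self):
        sp = build_state_space([("N", 4)])
        P = np.eye(4)
        omega = count_transitions([make_series([2, 2])], 1)
        ll, floored = log_likelihood(P, omega, sp)
        assert ll == 0.0 and floored == 0

    def test_arithmetic(self):
        sp = build_state_space([("N", 3)])
        P = np.array([[0.5, 0, 0], [0.25, 1, 0], [0.25, 0, 1]])
        omega = count_transitions([make_series([0, 0, 0, 1])], 1)
        ll, _ = log_likelihood(P, omega, sp)
        assert ll == pytest.approx(2 * np.log(0.5) + np.log(0.25))

    def test_zero_probability_floored_and_counted(self):
        sp = build_state_space([("N", 3)])
        P = np.eye(3)
        omega = count_transitions([make_series([0, 1])], 1)
        ll, floored = log_likelihood(P, omega, sp)
        assert floored == 1 and ll < -600

    def test_state_outside_range_rejected(self):
        sp = build_state_space([("N", 3)])
        omega = count_transitions([make_series([0, 5])], 1)
        with pytest.raises(ValueError, match="FSP bound"):
            log_likelihood(np.eye(4), omega, sp)

    def test_empirical_frequencies_maximize(self, rng):
        """Multinomial MLE identity: among all column-stochastic
        matrices, the empirical transition frequencies maximize the
        transition likelihood."""
        n = 4
        counts = rng.integers(0, 20, size=(n, n))
        sp = build_state_space([("N", n)])
        freqs = counts / np.maximum(counts.sum(axis=0), 1)
        src, dst = np.meshgrid(np.arange(n), np.arange(n))
        from maxcalbench.inference import TransitionCounts
        pairs = np.stack([src.ravel(), dst.ravel()], axis=1)
        omega = TransitionCounts(1, 300.0, 1, pairs, counts.T.ravel())
        ll_mle, _ = log_likelihood(freqs, omega, sp)
        for _ in range(20):
            P = rng.random((n, n))
            P /= P.sum(axis=0)
            ll, _ = log_likelihood(P, omega, sp)
            assert ll <= ll_mle + 1e-9


class TestMaximizeLikelihood:
    def test_birth_death_recovery_with_fixed_hill_term(self):
        """Data from a birth-death process, fitted over (g2, r2) with
        the Hill term clamped to zero, recovers both rates within 5%
        at ~1e5 pooled transitions."""
        lam, mu = 6.0e-3, 1.2e-3
        net = sgaa_cgm_network(CGMParamsSGAA(lam, 0.0, 100.0, mu))
        cfg = SimulationConfig(t_end=300.0 * 25_000 + 10.0, delta_t=300.0,
                               burn_in=0.0, n_trajectories=4, rng_seed=21)
        trajs = simulate_ssa(net, cfg)
        omega = count_transitions(trajs, 1)
        assert omega.n_transitions >= 100_000
        nmax = auto_nmax(omega.max_observed)
        space = build_state_space([("N", nmax)])

        def nll(vec):
            g2, r2 = np.exp(vec)
            P = observed_transition_matrix(
                "cgm", "sgaa", CGMParamsSGAA(g2, 0.0, 100.0, r2),
                space, 1, 300.0)
            return -log_likelihood(P, omega, space)[0]

        res = minimize(nll, np.log([4e-3, 2e-3]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8})
        g2_hat, r2_hat = np.exp(res.x)
        assert g2_hat == pytest.approx(lam, rel=0.05)
        assert r2_hat == pytest.approx(mu, rel=0.05)

    def test_fitted_likelihood_beats_truth(self):
        """The maximized likelihood is at least the likelihood at the
        generating parameters (optimality)."""
        truth = MaxCalParamsSGAA(-0.8, 1.0, 0.03, 8)
        sp = build_state_space([("N", 40)])
        chain = simulate_chain_sgaa(truth, sp, 5000, seed=3, N0=4)
        trajs = [FrameSeries(300.0, chain, ["A"])]
        omega = count_transitions(trajs, 1)
        space = model_state_space("maxcal", "sgaa", 40)
        init = initial_guesses("maxcal", "sgaa", trajs, 300.0)
        res = maximize_likelihood(
            "maxcal", "sgaa", omega, space, 300.0, 1,
            config=OptimizerConfig(n_starts=2, seed=1, M_grid=tuple(range(4, 12))),
            init=init)
        P_truth = observed_transition_matrix("maxcal", "sgaa", truth, space,
                                             1, 300.0)
        ll_truth, _ = log_likelihood(P_truth, omega, space)
        assert res.log_likelihood >= ll_truth - 1e-6
        assert res.converged

    def test_consistency_error_shrinks_with_data(self):
        """Fitting the MaxCal chain to its own trajectories: the median
        parameter error over seeds decreases monotonically as the data
        grow (three sizes, five seeds)."""
        truth = MaxCalParamsSGAA(-0.8, 1.0, 0.03, 8)
        sp = build_state_space([("N", 40)])
        space = model_state_space("maxcal", "sgaa", 40)
        sizes = (500, 4000, 32_000)
        med_errors = []
        for n_frames in sizes:
            errs = []
            for seed in range(5):
                chain = simulate_chain_sgaa(truth, sp, n_frames,
                                            seed=100 + seed, N0=4)
                trajs = [FrameSeries(300.0, chain, ["A"])]
                omega = count_transitions(trajs, 1)
                init = initial_guesses("maxcal", "sgaa", trajs, 300.0)
                res = maximize_likelihood(
                    "maxcal", "sgaa", omega, space, 300.0, 1,
                    config=OptimizerConfig(n_starts=1, seed=seed,
                                           M_grid=(8,)),
                    init=init)
                fitted = np.array([res.params["h_alpha"], res.params["h_A"],
                                   res.params["K_A"]])
                true_vec = np.array([-0.8, 1.0, 0.03])
                errs.append(np.abs((fitted - true_vec) / true_vec).max())
            med_errors.append(np.median(errs))
        assert med_errors[0] > med_errors[1] > med_errors[2]

    def test_unknown_model_rejected(self):
        sp = build_state_space([("N", 5)])
        omega = count_transitions([make_series([1, 2])], 1)
        with pytest.raises(ValueError):
            maximize_likelihood("ode", "sgaa", omega, sp, 300.0, 1,
                                init=None)


def test_initial_guesses_orders_of_magnitude(sgaa_48h_trajectories):
    """Method-of-moments starts land within an order of magnitude of the
    known effective rates of the default circuit."""
    init = initial_guesses("dm", "sgaa", sgaa_48h_trajectories, 300.0)
    assert 1e-3 < init.g1 < 2.5e-2
    assert 1e-2 < init.g1_star < 2.5e-1
    assert 1e-4 < init.r1 < 1e-2
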