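"""Hidden Markov idealization, transition densities and rate conversion."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import norm

import scrunchfret as sf
from scrunchfret.hmm import forward_log_likelihood


def brute_force_loglik(x, pi, A, means, sds):
    """Exhaustive sum over all K^T hidden paths (independent oracle)."""
    K, T = len(pi), len(x)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]] * norm.pdf(x[0], means[path[0]], sds[path[0]])
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * norm.pdf(x[t], means[path[t]], sds[path[t]])
        total += p
    return np.log(total)


TOY_PI = np.array([0.5, 0.3, 0.2])
TOY_A = np.array([[0.8, 0.15, 0.05], [0.1, 0.7, 0.2], [0.05, 0.25, 0.7]])
TOY_MEANS = np.array([0.14, 0.38, 0.56])
TOY_SDS = np.array([0.05, 0.07, 0.06])


class TestForwardOracle:
    @pytest.mark.parametrize("T", [1, 3, 5])
    def test_scaled_forward_equals_exhaustive_path_sum(self, T, rng):
        x = rng.uniform(0.0, 0.8, size=T)
        ours = forward_log_likelihood(x, TOY_PI, TOY_A, TOY_MEANS, TOY_SDS)
        ref = brute_force_loglik(x, TOY_PI, TOY_A, TOY_MEANS, TOY_SDS)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_agrees_with_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        x = rng.uniform(0.0, 0.8, size=200)
        m = hmmlearn.GaussianHMM(3, covariance_type="diag", init_params="")
        m.startprob_ = TOY_PI
        m.transmat_ = TOY_A
        m.means_ = TOY_MEANS[:, None]
        m.covars_ = (TOY_SDS**2)[:, None]
        ref = m.score(x[:, None])
        ours = forward_log_likelihood(x, TOY_PI, TOY_A, TOY_MEANS, TOY_SDS)
        assert ours == pytest.approx(ref, abs=1e-8)


class TestFitHMM:
    def test_single_state_data_gives_near_identity_transitions(self, rng):
        # all traces sit in one state; the second state starves and the fitted
        # transition matrix stays at the identity
        traces = [rng.normal(0.4, 0.05, 300) for _ in range(10)]
        fit = sf.fit_hmm(
            traces, n_states=2, seed=0, n_restarts=1, init_means=[0.4, 0.9]
        )
        i = int(np.argmax(fit.initial_probs))
        assert abs(fit.emission_means[i] - 0.4) < 0.01
        assert fit.transition_matrix[i, 1 - i] < 1e-3
        assert fit.transition_matrix[1 - i, i] < 1e-3

    def test_single_state_data_idealizes_without_transitions(self, rng):
        # even an unconstrained 2-state fit must not invent dynamics
        traces = [rng.normal(0.4, 0.05, 300) for _ in range(10)]
        fit = sf.fit_hmm(traces, n_states=2, seed=0)
        n_trans = sum(
            int(np.sum(np.diff(sf.viterbi_path(fit, t).state_id) != 0))
            for t in traces
        )
        assert n_trans / (10 * 300) < 0.01

    def test_wt_like_emission_mean_recovery(self, wt_fret):
        fit = sf.fit_hmm(wt_fret, n_states=3, seed=1)
        assert np.all(np.abs(fit.emission_means - [0.14, 0.38, 0.56]) < 0.02)
        assert np.allclose(fit.transition_matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_states_sorted_by_mean(self, wt_fret):
        fit = sf.fit_hmm(wt_fret, n_states=3, seed=2)
        assert np.all(np.diff(fit.emission_means) > 0)

    def test_needs_minimum_frames(self):
        with pytest.raises(sf.InvalidParameterError):
            sf.fit_hmm([np.array([0.1, 0.2])], n_states=3, seed=0)

    def test_variance_floor_flagged_on_noiseless_blocks(self):
        x = np.r_[np.full(50, 0.14), np.full(50, 0.56)]
        fit = sf.fit_hmm([x], n_states=2, seed=0)
        assert any("variance floor" in f for f in fit.flags)


class TestViterbi:
    def test_noiseless_blocks_recovered_exactly(self):
        fit = sf.HMMFit(
            n_states=3,
            emission_means=TOY_MEANS,
            emission_sds=np.full(3, 0.05),
            transition_matrix=TOY_A,
            initial_probs=np.full(3, 1 / 3),
            log_likelihood=0.0,
            n_traces_used=1,
        )
        truth = np.r_[np.zeros(20, int), np.full(15, 2), np.ones(10, int)]
        path = sf.viterbi_path(fit, TOY_MEANS[truth])
        assert np.array_equal(path.state_id, truth)

    def test_two_frame_toy_matches_exhaustive_argmax(self):
        pi = np.array([0.6, 0.4])
        A = np.array([[0.9, 0.1], [0.5, 0.5]])
        means = np.array([0.0, 1.0])
        sds = np.array([0.3, 0.3])
        fit = sf.HMMFit(2, means, sds, A, pi, 0.0, 1)
        x = np.array([0.45, 0.7])
        probs = {}
        for p in itertools.product(range(2), repeat=2):
            v = pi[p[0]] * norm.pdf(x[0], means[p[0]], sds[p[0]])
            v *= A[p[0], p[1]] * norm.pdf(x[1], means[p[1]], sds[p[1]])
            probs[p] = v
        best = max(probs, key=probs.get)
        path = sf.viterbi_path(fit, x)
        assert tuple(path.state_id) == best

    def test_tie_breaks_toward_lower_state(self):
        # emissions equidistant from both means, symmetric dynamics
        pi = np.array([0.5, 0.5])
        A = np.array([[0.5, 0.5], [0.5, 0.5]])
        fit = sf.HMMFit(2, np.array([0.2, 0.8]), np.array([0.1, 0.1]), A, pi, 0.0, 1)
        path = sf.viterbi_path(fit, np.full(5, 0.5))
        assert np.all(path.state_id == 0)

    def test_empty_trace_rejected(self, wt_fret):
        fit = sf.fit_hmm(wt_fret[:3], n_states=2, seed=0)
        with pytest.raises(sf.InvalidParameterError):
            sf.viterbi_path(fit, np.empty(0))


class TestTransitionDensity:
    def _fit(self):
        return sf.HMMFit(3, TOY_MEANS, np.full(3, 0.05), TOY_A,
                         np.full(3, 1 / 3), 0.0, 1)

    def _path(self, states):
        states = np.asarray(states, int)
        occ = np.eye(3)[states]
        return sf.StatePath(np.arange(len(states)), states, occ)

    def test_single_transition_single_point(self):
        td = sf.transition_density([self._path([1, 1, 2, 2])], self._fit())
        assert td.n_transitions == 1
        assert tuple(td.points[0]) == (0.38, 0.56)

    def test_constant_path_no_transitions(self):
        td = sf.transition_density([self._path([0] * 10)], self._fit())
        assert td.n_transitions == 0
        assert td.points.shape == (0, 2)

    def test_symmetric_path_density_symmetric(self):
        # equal numbers of forward and back transitions
        td = sf.transition_density([self._path([0, 1] * 10 + [0])], self._fit())
        assert td.n_transitions == 20
        assert np.allclose(td.grid, td.grid.T)

    def test_count_matches_state_changes(self, wt_fret):
        fit = sf.fit_hmm(wt_fret, n_states=3, seed=3)
        paths = [sf.viterbi_path(fit, ft) for ft in wt_fret]
        expected = sum(int(np.sum(p.state_id[1:] != p.state_id[:-1])) for p in paths)
        td = sf.transition_density(paths, fit)
        assert td.n_transitions == expected


class TestRatesFromHMM:
    def _fit_with(self, P):
        K = P.shape[0]
        return sf.HMMFit(K, np.linspace(0.1, 0.6, K), np.full(K, 0.05), P,
                         np.full(K, 1 / K), 0.0, 1)

    def test_identity_matrix_gives_zero_rates_and_flag(self):
        r = sf.rates_from_hmm(self._fit_with(np.eye(3)), 0.1)
        assert np.allclose(r.k, 0.0)
        assert np.isnan(r.keq_scrunch)
        assert any("keq undefined" in f for f in r.flags)

    def test_linear_method_definition(self):
        P = np.array([[0.99, 0.01], [0.02, 0.98]])
        r = sf.rates_from_hmm(self._fit_with(P), 0.1, method="linear")
        assert r.k[0, 1] == pytest.approx(0.1)
        assert r.k[1, 0] == pytest.approx(0.2)

    def test_exact_log_inverts_expm_exactly(self):
        Q = np.array([[-0.6, 0.4, 0.2], [0.3, -0.5, 0.2], [0.1, 0.6, -0.7]])
        dt = 0.1
        r = sf.rates_from_hmm(self._fit_with(expm(Q * dt)), dt, method="exact_log")
        assert np.allclose(r.k, Q, atol=1e-10)

    def test_exact_log_beats_linear_at_moderate_rates(self):
        # k*dt = 0.3: the linear approximation undercounts return transitions
        Q = np.array([[-3.0, 3.0], [3.0, -3.0]])
        dt = 0.1
        fit = self._fit_with(expm(Q * dt))
        exact = sf.rates_from_hmm(fit, dt, method="exact_log")
        lin = sf.rates_from_hmm(fit, dt, method="linear")
        assert abs(exact.k[0, 1] - 3.0) < 1e-8
        assert abs(lin.k[0, 1] - 3.0) > 0.3

    def test_keq_recovery_moderate_sim(self, wt_model, noiseless_phys):
        ts = sf.simulate_trace_set(wt_model, noiseless_phys, 40, 400, seed=31)
        fret = [sf.compute_fret(t) for t in ts]
        fit = sf.fit_hmm(fret, 3, seed=32)
        r = sf.rates_from_hmm(fit, 0.1)
        assert r.keq_scrunch == pytest.approx(6.0, rel=0.25)

    def test_keq_consistent_with_viterbi_occupancy(self, wt_fret):
        # scrunched/open occupancy ratio of the idealized paths ~ Keq
        fit = sf.fit_hmm(wt_fret, 3, seed=33)
        r = sf.rates_from_hmm(fit, 0.1)
        paths = np.concatenate([sf.viterbi_path(fit, ft).state_id for ft in wt_fret])
        occ_ratio = np.mean(paths == 2) / np.mean(paths == 1)
        assert r.keq_scrunch == pytest.approx(occ_ratio, rel=0.25)

    def test_invalid_frame_interval(self, wt_fret):
        fit = sf.fit_hmm(wt_fret[:3], n_states=2, seed=0)
        with pytest.raises(sf.InvalidParameterError):
            sf.rates_from_hmm(fit, 0.0)
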