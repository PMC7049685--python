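"""Three-state Gaussian-emission hidden Markov analysis of FRET traces.

Corrected FRET series are idealized with a hidden Markov model whose hidden
states are the closed, open and scrunched promoter conformations and whose
emissions are Gaussian per state.  One global model is fitted per condition
by maximum-likelihood Baum-Welch (EM) over the pooled multi-trace likelihood,
with scaled forward-backward recursions and seeded multi-start.  Idealized
Viterbi paths feed transition-density plots, and the fitted per-frame
transition matrix is converted to first-order rate constants — by default
through the matrix logarithm (exact for a time-homogeneous chain), with the
linear small-probability approximation k_ij = p_ij / dt available for
comparison — from which the scrunching equilibrium constant
Keq = k(open->scrunched) / k(scrunched->open) follows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np
import scipy.linalg

from .errors import ConvergenceError, InvalidParameterError
from .models import FretTrace, StatePath

__all__ = [
    "HMMFit",
    "fit_hmm",
    "viterbi_path",
    "TransitionDensity",
    "transition_density",
    "RateEstimates",
    "rates_from_hmm",
    "forward_log_likelihood",
]

_VAR_FLOOR = 1e-4  # emission variance floor (FRET units squared)


@dataclass
class HMMFit:
    """Pooled HMM parameters, states sorted by emission mean ascending."""

    n_states: int
    emission_means: np.ndarray
    emission_sds: np.ndarray
    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    log_likelihood: float
    n_traces_used: int
    n_iter: int = 0
    converged: bool = True
    flags: list = field(default_factory=list)


def _as_arrays(fret_traces) -> List[np.ndarray]:
    out = []
    for ft in fret_traces:
        x = ft.E if isinstance(ft, FretTrace) else np.asarray(ft, dtype=float)
        out.append(np.asarray(x, dtype=float))
    return out


def _emission_logpdf(x, means, var):
    # x: (...,) -> (..., K)
    d = x[..., None] - means
    return -0.5 * d * d / var - 0.5 * np.log(2 * np.pi * var)


def _batched_e_step(X, pi, A, means, var):
    """Scaled forward-backward on a stacked batch X of shape (B, T).

    Returns (loglik_total, gamma (B,T,K), xi_sum (K,K), gamma0_sum (K,)).
    """
    B, T = X.shape
    K = means.size
    logb = _emission_logpdf(X, means, var)  # (B,T,K)
    # scale emission densities per (trace, frame) to avoid under/overflow
    bmax = logb.max(axis=2, keepdims=True)
    bprob = np.exp(logb - bmax)  # (B,T,K)

    alpha = np.empty((B, T, K))
    c = np.empty((B, T))
    a = pi * bprob[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * bprob[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    loglik = float(np.sum(np.log(c)) + np.sum(bmax))

    beta = np.empty((B, T, K))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        nxt = bprob[:, t + 1] * beta[:, t + 1]  # (B,K)
        beta[:, t] = (nxt @ A.T) / c[:, t + 1, None]
        xi_sum += np.einsum("bi,bj->ij", alpha[:, t], nxt / c[:, t + 1, None]) * A
    gamma = alpha * beta
    return loglik, gamma, xi_sum, gamma[:, 0].sum(axis=0)


def forward_log_likelihood(
    x: np.ndarray,
    initial_probs: np.ndarray,
    transition_matrix: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
) -> float:
    """Scaled forward-pass log-likelihood of one observation sequence."""
    x = np.asarray(x, dtype=float)
    ll, *_ = _batched_e_step(
        x[None, :],
        np.asarray(initial_probs, float),
        np.asarray(transition_matrix, float),
        np.asarray(means, float),
        np.asarray(sds, float) ** 2,
    )
    return ll


def _sort_states(pi, A, means, var):
    order = np.argsort(means, kind="stable")
    return pi[order], A[np.ix_(order, order)], means[order], var[order]


def fit_hmm(
    fret_traces: Iterable,
    n_states: int = 3,
    n_restarts: int = 4,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed=None,
    init_means: Optional[np.ndarray] = None,
) -> HMMFit:
    """Baum-Welch fit of one Gaussian-emission HMM to a set of FRET traces.

    The pooled log-likelihood over all traces is maximised; its monotone
    increase is asserted at every EM iteration.  Traces are grouped by length
    and processed as stacked batches.  ``init_means`` seeds the emission
    means of the first restart (later restarts jitter quantile-spaced means).

    Raises :class:`ConvergenceError` (carrying the best fit so far) if no
    restart converges within ``max_iter`` iterations.
    """
    series = _as_arrays(fret_traces)
    series = [s for s in series if s.size >= 2 * n_states]
    if not series:
        raise InvalidParameterError(
            f"need at least one trace with >= {2 * n_states} frames"
        )
    pooled = np.concatenate(series)
    rng = np.random.default_rng(seed)

    # group traces by length for batched recursions
    groups = {}
    for s in series:
        groups.setdefault(s.size, []).append(s)
    batches = [np.stack(v) for v in groups.values()]

    def run_em(means0):
        K = n_states
        means = means0.copy()
        var = np.full(K, max(np.var(pooled) / K, _VAR_FLOOR))
        pi = np.full(K, 1.0 / K)
        A = np.full((K, K), 0.05 / max(K - 1, 1))
        np.fill_diagonal(A, 0.95)
        ll_old = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            ll = 0.0
            xi_sum = np.zeros((K, K))
            g0 = np.zeros(K)
            gsum = np.zeros(K)
            gx = np.zeros(K)
            gxx = np.zeros(K)
            for X in batches:
                l, gamma, xi, g0b = _batched_e_step(X, pi, A, means, var)
                ll += l
                xi_sum += xi
                g0 += g0b
                gsum += gamma.sum(axis=(0, 1))
                gx += np.einsum("btk,bt->k", gamma, X)
                gxx += np.einsum("btk,bt->k", gamma, X * X)
            # EM guarantees monotone likelihood; a violation is a bug
            assert ll >= ll_old - 1e-7 * max(1.0, abs(ll)), "EM likelihood decreased"
            # M-step; a starved state (no responsibility mass) keeps its
            # previous emission parameters and an identity transition row
            pi = g0 / g0.sum()
            row = xi_sum.sum(axis=1)
            occupied = gsum > 1e-10
            A = np.where(
                (row > 1e-10)[:, None],
                xi_sum / np.maximum(row, 1e-300)[:, None],
                np.eye(K),
            )
            means = np.where(occupied, gx / np.maximum(gsum, 1e-300), means)
            var_new = gxx / np.maximum(gsum, 1e-300) - (gx / np.maximum(gsum, 1e-300)) ** 2
            var = np.where(occupied, np.maximum(var_new, _VAR_FLOOR), var)
            if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
                converged = True
                ll_old = ll
                break
            ll_old = ll
        return pi, A, means, var, ll_old, converged, it

    q = np.quantile(pooled, (np.arange(n_states) + 0.5) / n_states)
    best = None
    any_conv = False
    for r in range(max(1, n_restarts)):
        if r == 0 and init_means is not None:
            m0 = np.asarray(init_means, dtype=float)
        elif r == 0:
            m0 = q.copy()
        else:
            m0 = q + rng.normal(0.0, 0.5 * max(pooled.std(), 1e-3), size=n_states)
        res = run_em(m0)
        any_conv = any_conv or res[5]
        if best is None or res[4] > best[4]:
            best = res
    pi, A, means, var, ll, conv, it = best
    pi, A, means, var = _sort_states(pi, A, means, var)
    flags = []
    if np.any(var <= _VAR_FLOOR + 1e-15):
        flags.append("variance floor active on at least one state")
    fit = HMMFit(
        n_states=n_states,
        emission_means=means,
        emission_sds=np.sqrt(var),
        transition_matrix=A,
        initial_probs=pi,
        log_likelihood=ll,
        n_traces_used=len(series),
        n_iter=it,
        converged=conv,
        flags=flags,
    )
    if not any_conv:
        raise ConvergenceError(
            f"Baum-Welch did not converge within {max_iter} iterations", best=fit
        )
    return fit


def viterbi_path(fit: HMMFit, trace) -> StatePath:
    """Most probable hidden-state sequence for one trace (log-space).

    Ties are broken toward the lower state index (the lower-FRET state).
    """
    x = trace.E if isinstance(trace, FretTrace) else np.asarray(trace, dtype=float)
    if x.size < 1:
        raise InvalidParameterError("trace must have at least one frame")
    K = fit.n_states
    var = fit.emission_sds**2
    logb = _emission_logpdf(x, fit.emission_means, var)  # (T,K)
    with np.errstate(divide="ignore"):
        logA = np.log(fit.transition_matrix)
        logpi = np.log(fit.initial_probs)
    T = x.size
    delta = logpi + logb[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # argmax takes the lowest index on ties
        delta = cand[back[t], np.arange(K)] + logb[t]
    states = np.empty(T, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]
    occ = np.zeros((T, K))
    occ[np.arange(T), states] = 1.0
    frames = (
        trace.retained_frames
        if isinstance(trace, FretTrace) and trace.retained_frames.size == T
        else np.arange(T)
    )
    return StatePath(frame_index=frames, state_id=states, occupancy=occ)


@dataclass
class TransitionDensity:
    """(E_before, E_after) points of all state changes plus a 2-D density."""

    points: np.ndarray  # (n, 2)
    grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_transitions: int


def transition_density(
    paths: Iterable[StatePath],
    fit: HMMFit,
    bins: int = 50,
    range_=((-0.2, 1.2), (-0.2, 1.2)),
) -> TransitionDensity:
    """Transition-density plot from idealized paths.

    One point per state change, at (mean of departing state, mean of arriving
    state); self-transitions are excluded.  The grid is a 2-D histogram over
    the FRET x FRET plane.
    """
    pts = []
    for p in paths:
        s = p.state_id
        changes = np.nonzero(s[1:] != s[:-1])[0]
        for i in changes:
            pts.append((fit.emission_means[s[i]], fit.emission_means[s[i + 1]]))
    points = np.asarray(pts, dtype=float).reshape(-1, 2)
    grid, xe, ye = np.histogram2d(
        points[:, 0], points[:, 1], bins=bins, range=range_
    )
    return TransitionDensity(
        points=points, grid=grid, x_edges=xe, y_edges=ye,
        n_transitions=len(points),
    )


@dataclass
class RateEstimates:
    """First-order rate constants (s^-1) and the scrunching equilibrium."""

    k: np.ndarray
    keq_scrunch: float
    frame_interval: float
    method: str
    flags: list = field(default_factory=list)


def rates_from_hmm(
    fit: HMMFit,
    frame_interval: float,
    method: str = "exact_log",
    open_state: int = -2,
    scrunched_state: int = -1,
) -> RateEstimates:
    """Convert per-frame transition probabilities to rate constants.

    ``exact_log`` takes the matrix logarithm of the transition matrix divided
    by the frame interval (projected onto a valid generator: negative
    off-diagonal entries floored at zero, flagged when nonnegligible);
    ``linear`` uses k_ij = p_ij / dt for i != j, valid when p_ij << 1.
    Keq is k(open->scrunched)/k(scrunched->open), with the open/scrunched
    states the two highest-FRET states by default.
    """
    if frame_interval <= 0:
        raise InvalidParameterError("frame_interval must be > 0")
    P = fit.transition_matrix
    K = fit.n_states
    flags = list(fit.flags)
    if method == "exact_log":
        L = scipy.linalg.logm(P)
        if np.max(np.abs(np.imag(L))) > 1e-8:
            flags.append("matrix logarithm not real; fell back to linear method")
            method = "linear"
        else:
            Q = np.real(L) / frame_interval
            off = Q[~np.eye(K, dtype=bool)]
            neg = off[off < 0]
            if neg.size and np.abs(neg).max() > 1e-6:
                flags.append(
                    f"negative off-diagonal generator entries floored "
                    f"(worst {neg.min():.3g} s^-1)"
                )
            Q = np.where(np.eye(K, dtype=bool), Q, np.clip(Q, 0.0, None))
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            k = Q
    if method == "linear":
        k = P / frame_interval
        np.fill_diagonal(k, 0.0)
        np.fill_diagonal(k, -k.sum(axis=1))
    elif method != "exact_log":
        raise InvalidParameterError(f"unknown method {method!r}")

    i_open = open_state % K
    i_scr = scrunched_state % K
    k_fwd = k[i_open, i_scr]
    k_rev = k[i_scr, i_open]
    if k_rev > 0 and k_fwd > 0:
        keq = k_fwd / k_rev
    else:
        keq = float("nan")
        flags.append("keq undefined: zero scrunching and/or unscrunching rate")
    return RateEstimates(
        k=k, keq_scrunch=keq, frame_interval=frame_interval,
        method=method, flags=flags,
    )
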