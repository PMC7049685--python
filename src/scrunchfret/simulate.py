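"""Synthetic-data generators.

Every input the analysis pipeline consumes can be generated here with full
seed control: smFRET donor/acceptor trace sets from a continuous-time Markov
model of the closed/open/scrunched promoter conformation, and titration /
kinetics datasets from the ensemble forward models (quadratic tight binding,
hyperbola, Michaelis-Menten, exponential decay).

State trajectories are simulated by exact-jump (Gillespie) sampling and then
integrated onto the camera frame grid as fractional occupancies, so a frame
containing a sub-frame transition carries the occupancy-weighted mixture of
state FRET means (motion blur) rather than a discretised jump.  Detected
intensities are rendered as the exact algebraic inverse of the leakage /
background correction applied downstream, so that a noiseless, background-free
rendering round-trips through the correction to machine precision.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .binding import (
    hyperbola_model,
    michaelis_menten_model,
    quadratic_binding_model,
    exponential_decay_model,
)
from .errors import InvalidParameterError, UnsupportedModelError
from .models import (
    KineticModel,
    PhotophysicsParams,
    StatePath,
    TitrationDataset,
    Trace,
    TraceSet,
)

__all__ = [
    "simulate_state_path",
    "render_trace",
    "simulate_trace_set",
    "generate_titration",
    "wt_pos2_model",
    "d12_pos2_model",
    "dna_only_model",
    "scenario_model",
]

# Default state FRET means/widths follow the reported peak positions of the
# free-DNA (0.14), open (0.38) and scrunched (0.56) populations.
DEFAULT_MEANS = (0.14, 0.38, 0.56)
DEFAULT_SD = 0.06


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_path(
    model: KineticModel,
    n_frames: int,
    frame_interval: float = 0.1,
    start_state: Union[str, int, None] = None,
    seed=None,
) -> StatePath:
    """Exact-jump CTMC trajectory integrated into per-frame occupancies.

    Parameters
    ----------
    start_state : state name or index; ``None`` draws the initial state from
        the stationary distribution of the rate matrix.
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    if frame_interval <= 0:
        raise InvalidParameterError("frame_interval must be > 0")
    rng = _rng(seed)
    q = model.rate_matrix
    k = model.n_states

    if start_state is None:
        s = int(rng.choice(k, p=model.stationary()))
    elif isinstance(start_state, str):
        s = model.index(start_state)
    else:
        s = int(start_state)

    total_time = n_frames * frame_interval
    occ = np.zeros((n_frames, k))
    t = 0.0
    while t < total_time:
        exit_rate = -q[s, s]
        if exit_rate <= 0:
            t_end = total_time
        else:
            t_end = min(t + rng.exponential(1.0 / exit_rate), total_time)
        # accumulate occupancy of state s over [t, t_end)
        f0 = int(t / frame_interval)
        f1 = min(int(np.ceil(t_end / frame_interval)), n_frames)
        for f in range(f0, f1):
            lo = max(t, f * frame_interval)
            hi = min(t_end, (f + 1) * frame_interval)
            if hi > lo:
                occ[f, s] += hi - lo
        if t_end >= total_time:
            break
        jump_p = q[s].copy()
        jump_p[s] = 0.0
        jump_p /= jump_p.sum()
        s = int(rng.choice(k, p=jump_p))
        t = t_end

    occ /= frame_interval
    # guard against accumulated float error before normalising exactly
    row = occ.sum(axis=1)
    if np.any(np.abs(row - 1.0) > 1e-9):
        raise RuntimeError("occupancy bookkeeping error")  # pragma: no cover
    occ /= row[:, None]
    return StatePath(
        frame_index=np.arange(n_frames),
        state_id=np.argmax(occ, axis=1),
        occupancy=occ,
        frame_interval=frame_interval,
    )


def render_trace(
    path: StatePath,
    model: KineticModel,
    phys: PhotophysicsParams,
    seed=None,
) -> Trace:
    """Render detected donor/acceptor intensities for a state path.

    Per frame the apparent FRET efficiency is the occupancy-weighted state
    mean plus Gaussian emission noise (variance blended across occupied
    states).  Intensities are then the exact inverse of the correction
    formula E = (I_A - leakage*I_D)/(I_D + I_A) at total intensity T:

        I_D = T (1 - E) / (1 + leakage),   I_A = T (E + leakage) / (1 + leakage)

    so correcting a noiseless, background-free rendering returns E exactly,
    whatever the leakage.  Photobleaching is a single exponential step per
    dye: after acceptor bleach the frame renders at E = 0; after donor bleach
    both channels fall to background.  Acceptor direct-excitation check
    frames are prepended and appended and flagged.
    """
    if path.occupancy.shape[1] != model.n_states:
        raise InvalidParameterError("state path and model state sets disagree")
    if phys.total_intensity < 0:
        raise InvalidParameterError("total_intensity must be >= 0")
    rng = _rng(seed)
    n = path.n_frames
    dt = path.frame_interval
    lk = phys.leakage
    T = phys.total_intensity

    e = path.occupancy @ model.fret_means
    evar = path.occupancy @ (model.fret_sd**2)
    if np.any(evar > 0):
        e = e + rng.normal(0.0, np.sqrt(evar))

    t_bleach_d = (
        rng.exponential(1.0 / phys.bleach_rate_d) if phys.bleach_rate_d > 0 else np.inf
    )
    t_bleach_a = (
        rng.exponential(1.0 / phys.bleach_rate_a) if phys.bleach_rate_a > 0 else np.inf
    )
    frame_t = np.arange(n) * dt
    a_bleached = frame_t >= t_bleach_a
    d_bleached = frame_t >= t_bleach_d

    e = np.where(a_bleached, 0.0, e)
    I_D = T * (1.0 - e) / (1.0 + lk)
    I_A = T * (e + lk) / (1.0 + lk)
    I_D = np.where(d_bleached, 0.0, I_D)
    I_A = np.where(d_bleached, 0.0, I_A)

    nc = phys.n_check_frames
    # direct red excitation: acceptor channel lights up iff the acceptor dye
    # survives; donor channel is dark
    start_a = np.full(nc, 0.0 if t_bleach_a <= 0 else T)
    end_time = n * dt
    end_a = np.full(nc, T if t_bleach_a > end_time else 0.0)
    I_D = np.concatenate([np.zeros(nc), I_D, np.zeros(nc)])
    I_A = np.concatenate([start_a, I_A, end_a])
    is_check = np.concatenate(
        [np.ones(nc, bool), np.zeros(n, bool), np.ones(nc, bool)]
    )

    I_D = I_D + phys.background_d
    I_A = I_A + phys.background_a
    if phys.noise_sd > 0:
        I_D = I_D + rng.normal(0.0, phys.noise_sd, size=I_D.shape)
        I_A = I_A + rng.normal(0.0, phys.noise_sd, size=I_A.shape)

    return Trace(
        frame=np.arange(len(I_D)),
        I_D=I_D,
        I_A=I_A,
        is_check_frame=is_check,
        meta={
            "t_bleach_d": t_bleach_d,
            "t_bleach_a": t_bleach_a,
            "frame_interval": dt,
        },
    )


def simulate_trace_set(
    model: KineticModel,
    phys: PhotophysicsParams,
    n_traces: int,
    n_frames: int,
    seed=None,
    start_state=None,
) -> TraceSet:
    """Independent traces with per-trace seeds derived from one master seed."""
    if n_traces < 1:
        raise InvalidParameterError("n_traces must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_traces)
    traces = []
    truth_paths = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        path = simulate_state_path(
            model, n_frames, phys.frame_interval, start_state=start_state, seed=rng
        )
        tr = render_trace(path, model, phys, seed=rng)
        tr.meta["trace_id"] = i
        traces.append(tr)
        truth_paths.append(path)
    manifest = {
        "seed": seed,
        "n_traces": n_traces,
        "n_frames": n_frames,
        "state_names": list(model.state_names),
        "fret_means": model.fret_means.tolist(),
        "fret_sd": model.fret_sd.tolist(),
        "rate_matrix": model.rate_matrix.tolist(),
        "photophysics": {
            "total_intensity": phys.total_intensity,
            "noise_sd": phys.noise_sd,
            "leakage": phys.leakage,
            "background_d": phys.background_d,
            "background_a": phys.background_a,
            "bleach_rate_d": phys.bleach_rate_d,
            "bleach_rate_a": phys.bleach_rate_a,
            "frame_interval": phys.frame_interval,
            "n_check_frames": phys.n_check_frames,
        },
    }
    ts = TraceSet(traces=traces, manifest=manifest)
    ts.truth_paths = truth_paths
    return ts


_TITRATION_MODELS = {
    "quadratic_binding": (
        quadratic_binding_model,
        ("K_d", "D_t", "r_f", "r_b"),
    ),
    "hyperbola": (hyperbola_model, ("F0", "dF", "K_d")),
    "michaelis_menten": (michaelis_menten_model, ("k_cat", "K_m")),
    "exponential_decay": (exponential_decay_model, ("amplitude", "k", "baseline")),
}


def generate_titration(
    kind: str,
    truth: dict,
    x,
    noise_sd: float = 0.0,
    seed=None,
    x_unit: str = "uM",
    y_kind: Optional[str] = None,
) -> TitrationDataset:
    """Evaluate a named forward model on a concentration/time grid + noise."""
    if kind not in _TITRATION_MODELS:
        raise UnsupportedModelError(
            f"unknown titration kind {kind!r}; choose from {sorted(_TITRATION_MODELS)}"
        )
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidParameterError("x grid must be nonempty")
    if np.any(x < 0):
        raise InvalidParameterError("x grid must be nonnegative")
    fn, pnames = _TITRATION_MODELS[kind]
    missing = [p for p in pnames if p not in truth]
    if missing:
        raise InvalidParameterError(f"truth parameters missing for {kind}: {missing}")
    y = fn(x, **{p: truth[p] for p in pnames})
    if noise_sd > 0:
        y = y + _rng(seed).normal(0.0, noise_sd, size=y.shape)
    default_kind = {
        "quadratic_binding": "anisotropy",
        "hyperbola": "fluorescence",
        "michaelis_menten": "rate",
        "exponential_decay": "fluorescence",
    }[kind]
    return TitrationDataset(
        x=x,
        y=y,
        y_err=np.full_like(y, noise_sd) if noise_sd > 0 else None,
        x_unit=x_unit,
        y_kind=y_kind or default_kind,
        meta={"model": kind, "truth": dict(truth), "noise_sd": noise_sd},
    )


# ---------------------------------------------------------------------------
# Named simulation scenarios
# ---------------------------------------------------------------------------

def dna_only_model(mean: float = DEFAULT_MEANS[0], sd: float = DEFAULT_SD) -> KineticModel:
    """Free promoter DNA: a single low-FRET state, no dynamics."""
    return KineticModel(["free_dna"], [mean], [sd], [[0.0]])


def _three_state(k_co, k_oc, k_os, k_so, means=DEFAULT_MEANS, sd=DEFAULT_SD):
    q = [
        [0.0, k_co, 0.0],
        [k_oc, 0.0, k_os],
        [0.0, k_so, 0.0],
    ]
    return KineticModel(
        ["closed", "open", "scrunched"], list(means), [sd] * 3, q
    )


def wt_pos2_model() -> KineticModel:
    """+2 initiation complex with full-length factor: scrunching-dominant.

    Linear closed <-> open <-> scrunched scheme; scrunching/unscrunching
    0.6/0.1 s^-1 gives the scrunching equilibrium constant Keq = 6.
    """
    return _three_state(k_co=0.2, k_oc=0.4, k_os=0.6, k_so=0.1)


def d12_pos2_model() -> KineticModel:
    """+2 complex with the 12-residue C-tail deletion: Keq = 1.5."""
    return _three_state(k_co=0.2, k_oc=0.4, k_os=0.6, k_so=0.4)


_SCENARIOS = {
    "dna_only": dna_only_model,
    "wt_pos2": wt_pos2_model,
    "d12_pos2": d12_pos2_model,
}


def scenario_model(name: str) -> KineticModel:
    """Look up a named simulation scenario's kinetic model."""
    try:
        return _SCENARIOS[name]()
    except KeyError:
        raise UnsupportedModelError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}"
        ) from None
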