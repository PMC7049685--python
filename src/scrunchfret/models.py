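"""Core domain containers.

The central object is :class:`KineticModel`, a continuous-time Markov model of
promoter-DNA conformation in the initiation complex (closed / open / scrunched),
with a FRET emission mean and width attached to each state.  The remaining
classes are light containers for simulated or measured data: per-frame
donor/acceptor traces, corrected FRET series, pooled FRET histograms and
(concentration, response) titration datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidModelError, InvalidParameterError

__all__ = [
    "KineticModel",
    "PhotophysicsParams",
    "StatePath",
    "Trace",
    "TraceSet",
    "FretTrace",
    "FRETHistogram",
    "TitrationDataset",
    "stationary_distribution",
]


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC generator matrix.

    Solves ``pi @ Q = 0`` with ``sum(pi) = 1`` via the null space of ``Q.T``.
    """
    Q = np.asarray(rate_matrix, dtype=float)
    k = Q.shape[0]
    # Append the normalisation constraint to the transposed generator.
    a = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass
class KineticModel:
    """Conformational states, FRET emission parameters and transition rates.

    Parameters
    ----------
    state_names : ordered state labels, low-FRET first (e.g. closed, open,
        scrunched).
    fret_means : FRET efficiency per state, strictly increasing with state
        order (dimensionless, in [0, 1]).
    fret_sd : per-state Gaussian emission standard deviation (dimensionless).
    rate_matrix : off-diagonal first-order rate constants k_ij (s^-1) for the
        i -> j transition; the diagonal is overwritten with minus the row sum.
    """

    state_names: Sequence[str]
    fret_means: np.ndarray
    fret_sd: np.ndarray
    rate_matrix: np.ndarray

    def __post_init__(self):
        self.state_names = list(self.state_names)
        self.fret_means = np.asarray(self.fret_means, dtype=float)
        self.fret_sd = np.asarray(self.fret_sd, dtype=float)
        q = np.array(self.rate_matrix, dtype=float)
        k = len(self.state_names)
        if q.shape != (k, k):
            raise InvalidModelError(
                f"rate_matrix shape {q.shape} does not match {k} states"
            )
        if self.fret_means.shape != (k,) or self.fret_sd.shape != (k,):
            raise InvalidModelError("fret_means/fret_sd must have one entry per state")
        off = q[~np.eye(k, dtype=bool)]
        if not np.all(np.isfinite(off)) or np.any(off < 0):
            raise InvalidModelError("off-diagonal rates must be finite and >= 0")
        if k > 1 and not np.all(np.diff(self.fret_means) > 0):
            raise InvalidModelError(
                "fret_means must be strictly increasing with state order"
            )
        if np.any(self.fret_sd < 0):
            raise InvalidModelError("fret_sd must be >= 0")
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        self.rate_matrix = q

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def stationary(self) -> np.ndarray:
        return stationary_distribution(self.rate_matrix)

    def index(self, name: str) -> int:
        return self.state_names.index(name)


@dataclass
class PhotophysicsParams:
    """Detection-channel photophysics of a TIRF smFRET measurement.

    total_intensity is the mean summed detected signal per frame (a.u.);
    noise_sd the per-channel additive Gaussian detection noise; leakage the
    donor->acceptor crosstalk fraction (0.08 in the correction formula);
    bleach_rate_d/_a single-step photobleaching rates (s^-1); n_check_frames
    the number of acceptor direct-excitation frames recorded at the start and
    at the end of each movie.
    """

    total_intensity: float = 1000.0
    noise_sd: float = 0.0
    leakage: float = 0.08
    background_d: float = 0.0
    background_a: float = 0.0
    bleach_rate_d: float = 0.0
    bleach_rate_a: float = 0.0
    frame_interval: float = 0.1
    n_check_frames: int = 5

    def __post_init__(self):
        if not 0 <= self.leakage < 1:
            raise InvalidParameterError(f"leakage must be in [0,1), got {self.leakage}")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if self.total_intensity < 0:
            raise InvalidParameterError("total_intensity must be >= 0")
        for name in ("noise_sd", "bleach_rate_d", "bleach_rate_a"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_check_frames < 0:
            raise InvalidParameterError("n_check_frames must be >= 0")


@dataclass
class StatePath:
    """Ground-truth state trajectory integrated onto the frame grid.

    ``occupancy`` has shape (n_frames, n_states); each row sums to 1 and gives
    the fraction of the frame interval spent in each state (sub-frame
    transitions produce fractional rows).  ``state_id`` is the
    majority-occupancy state of each frame.
    """

    frame_index: np.ndarray
    state_id: np.ndarray
    occupancy: np.ndarray
    frame_interval: float = 0.1

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.state_id = np.asarray(self.state_id, dtype=int)
        self.occupancy = np.asarray(self.occupancy, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def occupancy_fraction(self) -> np.ndarray:
        """Time-averaged occupancy of each state over the whole path."""
        return self.occupancy.mean(axis=0)


@dataclass
class Trace:
    """Detected per-frame donor/acceptor intensities of one molecule."""

    frame: np.ndarray
    I_D: np.ndarray
    I_A: np.ndarray
    is_check_frame: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frame = np.asarray(self.frame, dtype=int)
        self.I_D = np.asarray(self.I_D, dtype=float)
        self.I_A = np.asarray(self.I_A, dtype=float)
        self.is_check_frame = np.asarray(self.is_check_frame, dtype=bool)
        n = len(self.frame)
        if not (len(self.I_D) == len(self.I_A) == len(self.is_check_frame) == n):
            raise InvalidParameterError("trace columns must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.frame)

    @property
    def total(self) -> np.ndarray:
        return self.I_D + self.I_A


@dataclass
class TraceSet:
    """A collection of traces plus the manifest of how they were produced."""

    traces: list
    manifest: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, i):
        return self.traces[i]


@dataclass
class FretTrace:
    """Corrected FRET efficiency series of one molecule after QC."""

    E: np.ndarray
    retained_frames: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.retained_frames = np.asarray(self.retained_frames, dtype=int)

    @property
    def n_frames(self) -> int:
        return len(self.E)


@dataclass
class FRETHistogram:
    """Pooled, density-normalised histogram of windowed FRET values."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_traces: int
    n_points: int
    window: int
    values: Optional[np.ndarray] = None  # pooled window means, kept for refits

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))


@dataclass
class TitrationDataset:
    """(concentration, response) points with unit and response-kind tags.

    ``x_unit`` tags the abscissa ("nM", "uM" or "s" for time courses);
    ``y_kind`` names the response (anisotropy, fluorescence, rate).  ``meta``
    records the generating model and truth parameters for synthetic data.
    """

    x: np.ndarray
    y: np.ndarray
    y_err: Optional[np.ndarray] = None
    x_unit: str = "uM"
    y_kind: str = "fluorescence"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        order = np.argsort(np.asarray(self.x, dtype=float), kind="stable")
        self.x = np.asarray(self.x, dtype=float)[order]
        self.y = np.asarray(self.y, dtype=float)[order]
        if self.y_err is not None:
            self.y_err = np.asarray(self.y_err, dtype=float)[order]
        if np.any(self.x < 0):
            raise InvalidParameterError("concentrations/times must be >= 0")
        if not np.all(np.isfinite(self.y)):
            raise InvalidParameterError("responses must be finite")

    def __len__(self):
        return len(self.x)
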