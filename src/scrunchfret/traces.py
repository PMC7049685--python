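"""Trace processing: FRET correction, QC selection and histogram building.

Raw donor/acceptor intensity traces are converted to corrected FRET series

    E = (I_A - leakage * I_D) / (I_D + I_A),   leakage = 0.08 by default,

with I_D and I_A background-subtracted and acceptor direct-excitation check
frames excluded.  Traces are then filtered (acceptor present in the check
frames; a single photobleaching step at most on total intensity; visited the
mid-FRET band at least once) and pooled into density-normalised histograms of
non-overlapping five-frame window means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import EmptyTraceError, InvalidParameterError
from .models import FretTrace, FRETHistogram, Trace, TraceSet

__all__ = [
    "compute_fret",
    "QCConfig",
    "select_traces",
    "count_intensity_steps",
    "build_histogram",
]

DEFAULT_LEAKAGE = 0.08
# soft physical band for corrected FRET: values outside are flagged, not cut
SOFT_BAND = (-0.2, 1.2)


def compute_fret(
    trace: Trace,
    leakage: float = DEFAULT_LEAKAGE,
    background_d: float = 0.0,
    background_a: float = 0.0,
    min_total: Optional[float] = None,
) -> FretTrace:
    """Corrected FRET efficiency per frame.

    Frames whose background-subtracted total intensity falls below
    ``min_total`` are dropped (default: 10% of the median total over
    non-check frames — this removes post-donor-bleach tails).  Check frames
    are always excluded.  Frames outside the soft physical band [-0.2, 1.2]
    are counted in ``meta['n_outside_band']`` but retained.
    """
    if not 0 <= leakage < 1:
        raise InvalidParameterError("leakage must be in [0,1)")
    if not (np.isfinite(background_d) and np.isfinite(background_a)):
        raise InvalidParameterError("backgrounds must be finite")
    sel = ~trace.is_check_frame
    i_d = trace.I_D[sel] - background_d
    i_a = trace.I_A[sel] - background_a
    frames = trace.frame[sel]
    total = i_d + i_a
    if min_total is None:
        med = float(np.median(total)) if total.size else 0.0
        min_total = 0.1 * med
    keep = total > max(min_total, 1e-300)
    if not np.any(keep):
        raise EmptyTraceError("all frames below the intensity floor")
    E = (i_a[keep] - leakage * i_d[keep]) / total[keep]
    lo, hi = SOFT_BAND
    meta = dict(trace.meta)
    meta["n_outside_band"] = int(np.sum((E < lo) | (E > hi)))
    meta["leakage"] = leakage
    return FretTrace(E=E, retained_frames=frames[keep], meta=meta)


# ---------------------------------------------------------------------------
# QC selection
# ---------------------------------------------------------------------------

def count_intensity_steps(
    x: np.ndarray,
    min_segment: int = 5,
    z_threshold: float = 5.0,
    drops_only: bool = True,
) -> int:
    """Count significant mean-shift change points in a 1-D signal.

    Binary segmentation: recursively split at the point giving the largest
    reduction in squared error, accepting a split when the mean shift exceeds
    ``z_threshold`` noise units (noise estimated from first differences).
    With ``drops_only`` only downward steps are counted — the photobleaching
    signature on total intensity.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * min_segment:
        return 0
    noise = 1.4826 * float(np.median(np.abs(np.diff(x)))) / np.sqrt(2.0)
    noise = max(noise, 1e-12 * max(1.0, float(np.abs(x).max())))

    steps = []

    def split(lo, hi):
        n = hi - lo
        if n < 2 * min_segment:
            return
        seg = x[lo:hi]
        csum = np.cumsum(seg)
        tot = csum[-1]
        idx = np.arange(min_segment, n - min_segment + 1)
        mu1 = csum[idx - 1] / idx
        mu2 = (tot - csum[idx - 1]) / (n - idx)
        # z-score of the mean shift at each candidate split
        z = np.abs(mu1 - mu2) / (noise * np.sqrt(1.0 / idx + 1.0 / (n - idx)))
        j = int(np.argmax(z))
        if z[j] < z_threshold:
            return
        cut = lo + int(idx[j])
        steps.append((cut, float(mu2[j] - mu1[j])))
        split(lo, cut)
        split(cut, hi)

    split(0, x.size)
    if drops_only:
        return sum(1 for _, d in steps if d < 0)
    return len(steps)


@dataclass
class QCConfig:
    """Trace-selection filters; each can be disabled independently.

    acceptor_threshold: minimum background-subtracted acceptor signal in the
        direct-excitation check frames (a.u.); ``None`` uses 10% of the
        median per-trace total intensity of the input set.
    mid_fret_band: (lo, hi) FRET band that must be visited at least once —
        the open-complex band; default open mean +/- 2 sigma.
    """

    require_acceptor: bool = True
    acceptor_threshold: Optional[float] = None
    single_pair: bool = True
    max_bleach_steps: int = 1
    min_segment: int = 5
    z_threshold: float = 5.0
    require_mid_fret: bool = False
    mid_fret_band: tuple = (0.38 - 2 * 0.06, 0.38 + 2 * 0.06)
    leakage: float = DEFAULT_LEAKAGE
    background_d: float = 0.0
    background_a: float = 0.0


def select_traces(traces, criteria: Optional[QCConfig] = None):
    """Apply QC filters; returns (accepted TraceSet, rejection-log DataFrame).

    Filters are independent predicates evaluated on every trace, so the
    accepted set does not depend on any filter ordering.  The log has one row
    per trace with a boolean per filter and a combined rejection reason.
    """
    criteria = criteria or QCConfig()
    trace_list = list(traces)
    manifest = traces.manifest if isinstance(traces, TraceSet) else {}

    thr = criteria.acceptor_threshold
    if thr is None:
        medians = [
            float(np.median(t.total[~t.is_check_frame])) for t in trace_list
        ] or [0.0]
        thr = 0.1 * float(np.median(medians))

    rows = []
    accepted = []
    for i, tr in enumerate(trace_list):
        reasons = []
        ok_acceptor = ok_pair = ok_mid = True
        if criteria.require_acceptor:
            chk = tr.is_check_frame
            sig = float(np.mean(tr.I_A[chk] - criteria.background_a)) if chk.any() else 0.0
            ok_acceptor = sig > thr
            if not ok_acceptor:
                reasons.append("no acceptor")
        if criteria.single_pair:
            n_steps = count_intensity_steps(
                tr.total[~tr.is_check_frame],
                min_segment=criteria.min_segment,
                z_threshold=criteria.z_threshold,
            )
            ok_pair = n_steps <= criteria.max_bleach_steps
            if not ok_pair:
                reasons.append(f"multiple bleach steps ({n_steps})")
        if criteria.require_mid_fret:
            try:
                ft = compute_fret(
                    tr,
                    leakage=criteria.leakage,
                    background_d=criteria.background_d,
                    background_a=criteria.background_a,
                )
                lo, hi = criteria.mid_fret_band
                ok_mid = bool(np.any((ft.E >= lo) & (ft.E <= hi)))
            except EmptyTraceError:
                ok_mid = False
            if not ok_mid:
                reasons.append("never visited mid-FRET band")
        ok = ok_acceptor and ok_pair and ok_mid
        rows.append(
            {
                "trace": tr.meta.get("trace_id", i),
                "accepted": ok,
                "acceptor_present": ok_acceptor,
                "single_pair": ok_pair,
                "mid_fret_visited": ok_mid,
                "reason": "; ".join(reasons),
            }
        )
        if ok:
            accepted.append(tr)
    log = pd.DataFrame(rows)
    return TraceSet(traces=accepted, manifest=dict(manifest)), log


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

def window_means(E: np.ndarray, window: int) -> np.ndarray:
    """Non-overlapping window means; trailing partial windows are dropped."""
    if window < 1:
        raise InvalidParameterError("window must be >= 1")
    n = (len(E) // window) * window
    if n == 0:
        return np.empty(0)
    return np.asarray(E[:n], dtype=float).reshape(-1, window).mean(axis=1)


def build_histogram(
    fret_traces: Iterable[FretTrace],
    window: int = 5,
    bins=40,
    range_=SOFT_BAND,
) -> FRETHistogram:
    """Pooled density histogram of per-trace non-overlapping window means."""
    if window < 1:
        raise InvalidParameterError("window must be >= 1")
    traces = list(fret_traces)
    if not traces:
        raise InvalidParameterError("need at least one retained trace")
    pooled = np.concatenate([window_means(ft.E, window) for ft in traces])
    if pooled.size == 0:
        raise EmptyTraceError("no complete windows in any trace")
    density, edges = np.histogram(pooled, bins=bins, range=range_, density=True)
    return FRETHistogram(
        bin_edges=edges,
        density=density,
        n_traces=len(traces),
        n_points=int(pooled.size),
        window=window,
        values=pooled,
    )
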