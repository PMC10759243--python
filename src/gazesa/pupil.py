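"""Pupillogram preprocessing.

The pupil-diameter stream from a screen-mounted tracker is interrupted by
blinks and track loss and carries sample-to-sample measurement noise.  The
preprocessing chain applied here, per eye and then binocularly, is:

1. **gap interpolation** — each interior gap no longer than ``max_gap_ms``
   is filled with a line whose slope is estimated by least squares from the
   ``half_window`` valid samples on each side of the gap (10 + 10 = 20
   flanking points by default, the gap anchor making the 21st), anchored to
   pass through the last valid sample before the gap;
2. **Savitzky-Golay smoothing** — local least-squares polynomial smoothing
   (window 21 samples, cubic by default); missing spans stay missing;
3. **binocular averaging** — pointwise mean of the eyes where both are
   present, the single present value otherwise;
4. **baseline adjustment** — subtract the mean diameter over a baseline
   window (first 5 s by default), yielding *change in pupil diameter* (mm);
5. **normalization** — divide the baselined values by the baseline, giving
   a dimensionless relative change for cross-participant comparison.

Dilation relative to baseline indexes cognitive load/arousal; constriction
or flat response during a demanding episode suggests reduced engagement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import GazeRecording

logger = logging.getLogger(__name__)

MEASURED, INTERPOLATED, MISSING = 0, 1, 2
_STAGES = ["raw", "filled", "smoothed", "averaged", "baselined", "normalized"]

DEFAULT_HALF_WINDOW = 10
DEFAULT_MAX_GAP_MS = 500.0
DEFAULT_SG_WINDOW = 21
DEFAULT_SG_ORDER = 3
DEFAULT_BASELINE_MS = (0.0, 5000.0)


class AlignmentError(ValueError):
    """Two traces do not share a time base."""


@dataclass
class PupilTrace:
    """A pupil-diameter time series with per-point provenance.

    ``d`` is in millimetres up to the baselining stage, millimetre *change*
    after it; ``d_norm`` (present after normalization) is the dimensionless
    relative change.  ``mask`` codes each point as MEASURED, INTERPOLATED or
    MISSING; missing points hold NaN in ``d``.
    """

    t_ms: np.ndarray
    d: np.ndarray
    mask: np.ndarray
    stage: str = "raw"
    d_norm: np.ndarray | None = None
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, float)
        self.d = np.asarray(self.d, float)
        self.mask = np.asarray(self.mask)
        if len(self.t_ms) > 1 and np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("trace timestamps must be strictly increasing")
        if not (len(self.t_ms) == len(self.d) == len(self.mask)):
            raise ValueError("t, d and mask must have equal length")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.history:
            self.history = [self.stage]

    @property
    def present(self) -> np.ndarray:
        return self.mask != MISSING

    def _advance(self, stage: str, d=None, mask=None, d_norm=None) -> "PupilTrace":
        if _STAGES.index(stage) < _STAGES.index(self.stage):
            raise ValueError(
                f"stage {stage!r} cannot follow {self.stage!r} in the pipeline"
            )
        return PupilTrace(
            t_ms=self.t_ms,
            d=self.d if d is None else d,
            mask=self.mask if mask is None else mask,
            stage=stage,
            d_norm=self.d_norm if d_norm is None else d_norm,
            history=self.history + [stage],
        )


def trace_from_recording(recording: GazeRecording, eye: str) -> PupilTrace:
    """Raw per-eye pupil trace from a recording ('left' or 'right')."""
    col = {"left": "pupil_l", "right": "pupil_r"}[eye]
    vcol = {"left": "valid_l", "right": "valid_r"}[eye]
    df = recording.samples
    d = df[col].to_numpy(float).copy()
    valid = df[vcol].to_numpy(bool) & np.isfinite(d)
    d[~valid] = np.nan
    mask = np.where(valid, MEASURED, MISSING)
    return PupilTrace(df["t_ms"].to_numpy(float), d, mask, stage="raw")


def _gap_runs(missing: np.ndarray):
    """(start, stop) index pairs of maximal missing runs, stop exclusive."""
    padded = np.concatenate([[False], missing, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    return list(zip(starts, stops))


def interpolate_gaps(
    trace: PupilTrace,
    half_window: int = DEFAULT_HALF_WINDOW,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
) -> PupilTrace:
    """Fill interior gaps with a locally estimated line.

    The line's slope is the least-squares slope through the ``half_window``
    valid points on each side of the gap and the line passes through the
    last valid point before the gap.  Gaps at the trace extremes, longer
    than ``max_gap_ms``, or with too few flanking points stay missing.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    t, d, mask = trace.t_ms, trace.d.copy(), trace.mask.copy()
    missing = ~np.isfinite(d)
    valid_idx = np.nonzero(~missing)[0]
    for start, stop in _gap_runs(missing):
        if start == 0 or stop == len(d):
            continue  # edge gap: nothing to anchor to on one side
        span_ms = t[stop] - t[start - 1]
        if span_ms > max_gap_ms:
            continue
        before = valid_idx[valid_idx < start][-half_window:]
        after = valid_idx[valid_idx >= stop][:half_window]
        if len(before) < half_window or len(after) < half_window:
            logger.warning(
                "gap at %.1f ms left unfilled: fewer than %d valid points "
                "on one side",
                t[start],
                half_window,
            )
            continue
        flank = np.concatenate([before, after])
        slope = np.polyfit(t[flank], d[flank], 1)[0]
        anchor = start - 1
        idx = np.arange(start, stop)
        d[idx] = d[anchor] + slope * (t[idx] - t[anchor])
        mask[idx] = INTERPOLATED
    return trace._advance("filled", d=d, mask=mask)


def smooth_sg(
    trace: PupilTrace,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_ORDER,
) -> PupilTrace:
    """Savitzky-Golay smoothing of the present points.

    Applied independently to each contiguous present segment; missing spans
    propagate unchanged.  Edges (and segments shorter than the window) are
    handled by a least-squares polynomial fit on the truncated window.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window >= len(trace.t_ms):
        raise ValueError("window must be shorter than the trace")
    d = trace.d.copy()
    present = np.isfinite(d)
    for start, stop in _gap_runs(present):  # runs of PRESENT points
        seg = d[start:stop]
        n = len(seg)
        if n >= window:
            d[start:stop] = savgol_filter(seg, window, polyorder, mode="interp")
        elif n > 2:
            order = min(polyorder, n - 1)
            ts = trace.t_ms[start:stop]
            ts0 = ts - ts[0]
            coef = np.polyfit(ts0, seg, order)
            d[start:stop] = np.polyval(coef, ts0)
        # n <= 2: too short to smooth, left as-is
    return trace._advance("smoothed", d=d)


def average_binocular(left: PupilTrace, right: PupilTrace) -> PupilTrace:
    """Pointwise binocular mean; single-eye value where only one is present."""
    if len(left.t_ms) != len(right.t_ms) or not np.allclose(
        left.t_ms, right.t_ms
    ):
        raise AlignmentError("left and right traces have different time bases")
    dl, dr = left.d, right.d
    pl, pr = np.isfinite(dl), np.isfinite(dr)
    d = np.full(len(dl), np.nan)
    both = pl & pr
    d[both] = 0.5 * (dl[both] + dr[both])
    d[pl & ~pr] = dl[pl & ~pr]
    d[pr & ~pl] = dr[pr & ~pl]
    mask = np.minimum(left.mask, right.mask)  # MEASURED < INTERPOLATED < MISSING
    mask[~(pl | pr)] = MISSING
    out = PupilTrace(
        t_ms=left.t_ms,
        d=d,
        mask=mask,
        stage="averaged",
        history=left.history + ["averaged"],
    )
    return out


def baseline_normalize(
    trace: PupilTrace, baseline_window: tuple = DEFAULT_BASELINE_MS
) -> PupilTrace:
    """Subtract the baseline-window mean; also report relative change.

    Baselined values (``d``) are change in pupil diameter in mm; ``d_norm``
    is the same change divided by the baseline.
    """
    start, end = baseline_window
    sel = (trace.t_ms >= start) & (trace.t_ms < end) & np.isfinite(trace.d)
    if not sel.any():
        raise ValueError("baseline window contains no valid pupil data")
    span = trace.t_ms[sel][-1] - trace.t_ms[sel][0]
    if span < 1000.0:
        logger.warning(
            "baseline window holds only %.0f ms of valid data", span
        )
    b = float(np.mean(trace.d[sel]))
    baselined = trace.d - b
    return trace._advance("normalized", d=baselined, d_norm=baselined / b)


def pupillogram(
    recording: GazeRecording,
    half_window: int = DEFAULT_HALF_WINDOW,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_order: int = DEFAULT_SG_ORDER,
    baseline_window: tuple = DEFAULT_BASELINE_MS,
) -> PupilTrace:
    """Full preprocessing chain from a raw recording to a normalized trace.

    Per-eye gap interpolation and smoothing, then binocular averaging,
    baseline adjustment and normalization.  Stage provenance is kept in
    ``history``.
    """
    traces = []
    for eye in ("left", "right"):
        raw = trace_from_recording(recording, eye)
        if np.isfinite(raw.d).sum() == 0:
            continue
        filled = interpolate_gaps(raw, half_window, max_gap_ms)
        traces.append(smooth_sg(filled, sg_window, sg_order))
    if not traces:
        raise ValueError("recording has no pupil data in either eye")
    if len(traces) == 2:
        averaged = average_binocular(traces[0], traces[1])
    else:
        only = traces[0]
        averaged = only._advance("averaged")
    return baseline_normalize(averaged, baseline_window)
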