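"""Velocity-threshold (I-VT) fixation classification.

Gaze samples whose point-to-point speed is *strictly below* a velocity
threshold are fixation samples; samples at or above it are saccade samples.
The default threshold is 0.42 pixels per millisecond, the value used by
screen-mounted tracker analysis software for spatial fixation filtering at
high sampling rates.  Speeds are computed between consecutive *valid*
samples, so short track-loss gaps (blinks) are bridged when the implied
speed across the gap stays below threshold and the gap does not exceed
``max_gap_ms``; longer gaps always terminate a fixation.

Candidate fixations shorter than ``min_fix_ms`` are discarded (re-labelled
as saccade time), following standard minimum-duration practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GazeRecording

#: default I-VT speed threshold, pixels per millisecond
DEFAULT_THRESHOLD_PX_PER_MS = 0.42
DEFAULT_MIN_FIX_MS = 60.0
DEFAULT_MAX_GAP_MS = 75.0


class InsufficientDataError(ValueError):
    """Too few valid samples to compute gaze kinematics."""


@dataclass(frozen=True)
class Fixation:
    """A classified stable-gaze event.

    ``index`` is the 1-based rank in onset order; ``cx, cy`` is the centroid
    of the member samples in screen pixels.
    """

    index: int
    onset_ms: float
    offset_ms: float
    cx: float
    cy: float
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ValueError("fixation onset must precede offset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class VelocitySeries:
    """Per-sample gaze speed in px/ms, aligned to the recording's samples.

    ``speed[i]`` is the speed between samples i-1 and i; NaN where undefined
    (first sample, either sample invalid, or inter-sample gap > max_gap_ms).
    """

    t_ms: np.ndarray
    speed: np.ndarray
    max_gap_ms: float


def _valid_mask(recording: GazeRecording) -> np.ndarray:
    df = recording.samples
    xy_ok = np.isfinite(df["x"].to_numpy(float)) & np.isfinite(
        df["y"].to_numpy(float)
    )
    return (
        df["valid_l"].to_numpy(bool) | df["valid_r"].to_numpy(bool)
    ) & xy_ok


def compute_velocity(
    recording: GazeRecording, max_gap_ms: float = DEFAULT_MAX_GAP_MS
) -> VelocitySeries:
    """Point-to-point gaze speed between adjacent samples.

    Raises
    ------
    InsufficientDataError
        If the recording holds fewer than two valid samples.
    """
    if max_gap_ms <= 0:
        raise ValueError("max_gap_ms must be positive")
    valid = _valid_mask(recording)
    if valid.sum() < 2:
        raise InsufficientDataError("need at least 2 valid samples")
    df = recording.samples
    t = df["t_ms"].to_numpy(float)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    speed = np.full(len(t), np.nan)
    dt = np.diff(t)
    dist = np.hypot(np.diff(x), np.diff(y))
    ok = valid[1:] & valid[:-1] & (dt <= max_gap_ms)
    speed[1:][ok] = dist[ok] / dt[ok]
    return VelocitySeries(t_ms=t, speed=speed, max_gap_ms=max_gap_ms)


def _links(recording: GazeRecording, threshold: float, max_gap_ms: float):
    """Classify each interval between consecutive valid samples.

    Returns (t_valid, x_valid, y_valid, labels) where labels[j] describes the
    interval between valid samples j and j+1: 0 = fixation-continuing,
    1 = saccade, 2 = gap (track loss longer than max_gap_ms).
    """
    valid = _valid_mask(recording)
    if valid.sum() < 2:
        raise InsufficientDataError("need at least 2 valid samples")
    df = recording.samples
    t = df["t_ms"].to_numpy(float)[valid]
    x = df["x"].to_numpy(float)[valid]
    y = df["y"].to_numpy(float)[valid]
    dt = np.diff(t)
    speed = np.hypot(np.diff(x), np.diff(y)) / dt
    labels = np.where(dt > max_gap_ms, 2, np.where(speed < threshold, 0, 1))
    return t, x, y, labels


def detect_fixations_ivt(
    recording: GazeRecording,
    threshold_px_per_ms: float = DEFAULT_THRESHOLD_PX_PER_MS,
    min_fix_ms: float = DEFAULT_MIN_FIX_MS,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
) -> list:
    """Classify a recording into time-ordered fixations.

    Maximal runs of below-threshold intervals become candidate fixations;
    candidates shorter than ``min_fix_ms`` are discarded.  The centroid is
    the mean position of the member valid samples.
    """
    if threshold_px_per_ms <= 0:
        raise ValueError("threshold must be positive")
    t, x, y, labels = _links(recording, threshold_px_per_ms, max_gap_ms)
    fixations: list = []
    n_links = len(labels)
    j = 0
    while j < n_links:
        if labels[j] != 0:
            j += 1
            continue
        k = j
        while k < n_links and labels[k] == 0:
            k += 1
        # valid samples j .. k form the candidate run
        onset, offset = t[j], t[k]
        if offset - onset >= min_fix_ms:
            fixations.append(
                Fixation(
                    index=len(fixations) + 1,
                    onset_ms=float(onset),
                    offset_ms=float(offset),
                    cx=float(np.mean(x[j : k + 1])),
                    cy=float(np.mean(y[j : k + 1])),
                    n_samples=int(k - j + 1),
                )
            )
        j = k
    return fixations


def classify_segments(
    recording: GazeRecording,
    threshold_px_per_ms: float = DEFAULT_THRESHOLD_PX_PER_MS,
    min_fix_ms: float = DEFAULT_MIN_FIX_MS,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
) -> pd.DataFrame:
    """Partition the recording span into fixation / saccade / gap segments.

    Segment durations sum exactly to the recording span (first to last
    sample).  Candidate fixations shorter than ``min_fix_ms`` are counted as
    saccade time; leading/trailing invalid stretches are gap time.
    """
    t_all = recording.samples["t_ms"].to_numpy(float)
    t, _, _, labels = _links(recording, threshold_px_per_ms, max_gap_ms)
    segments = []

    def push(kind, start, end):
        if end > start:
            segments.append({"kind": kind, "start_ms": start, "end_ms": end})

    push("gap", t_all[0], t[0])
    j = 0
    n_links = len(labels)
    while j < n_links:
        lab = labels[j]
        k = j
        while k < n_links and labels[k] == lab:
            k += 1
        kind = {0: "fixation", 1: "saccade", 2: "gap"}[int(lab)]
        if kind == "fixation" and t[k] - t[j] < min_fix_ms:
            kind = "saccade"
        push(kind, t[j], t[k])
        j = k
    push("gap", t[-1], t_all[-1])
    df = pd.DataFrame(segments, columns=["kind", "start_ms", "end_ms"])
    df["duration_ms"] = df["end_ms"] - df["start_ms"]
    return df
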