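"""Expert-baseline attention monitoring and alerting.

The monitoring-centre feedback loop proposed here compares a subject's
rolling ocular activity against a baseline built from expert recordings of
the same scenario.  Three alert paths are implemented over sliding windows:

* **attention_deviation** — a monitored AOI's percent-fixation metric falls
  more than ``k_sigma`` dispersions *below* its expert baseline (deficit
  only: the concern is attention that is missing, not surplus);
* **track_loss** — the window's valid-sample fraction drops below
  ``min_valid_fraction`` (eyes closed or away from the screen: the tracker
  captures neither fixations nor pupil size);
* **pupil_constriction** — the baselined pupil level falls below a negative
  threshold, a cue of reduced alertness.

Raised alerts are rate-limited to ``max_alert_rate`` per 10-minute span,
keeping the highest-severity ones, following the human-factors guideline
that about one alarm per ten minutes is the acceptable ceiling for
monitoring personnel.

Real-time streaming is emulated as windowed batch processing over a
recorded stream; scenario phases (e.g. pre-anomaly / anomaly / recovery)
come from the scenario configuration, and windows that straddle a phase
boundary are skipped rather than compared against a mixed baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pupil as _pupil
from .aoi import percent_metrics
from .fixation import (
    DEFAULT_MAX_GAP_MS,
    DEFAULT_MIN_FIX_MS,
    DEFAULT_THRESHOLD_PX_PER_MS,
    detect_fixations_ivt,
)
from .io import AOIScheme, GazeRecording

logger = logging.getLogger(__name__)

TEN_MINUTES_MS = 600_000.0


@dataclass(frozen=True)
class Phase:
    name: str
    start_ms: float
    end_ms: float


def scenario_phases(anomaly_ms=(120_000.0, 170_000.0), duration_ms=300_000.0):
    """Default phase layout: pre-anomaly / anomaly / recovery."""
    a0, a1 = anomaly_ms
    return [
        Phase("pre", 0.0, a0),
        Phase("anomaly", a0, a1),
        Phase("post", a1, duration_ms),
    ]


@dataclass
class BaselineProfile:
    """Expected ocular activity per (phase, AOI), with dispersion.

    ``table`` columns: phase, aoi_name, metric, mean, dispersion.  With a
    single expert recording the dispersion falls back to
    ``dispersion_floor`` (percentage points).
    """

    phases: list
    table: pd.DataFrame
    expected_valid_fraction: float
    dispersion_floor: float
    source: list = field(default_factory=list)

    def lookup(self, phase: str, aoi: str, metric: str):
        rows = self.table[
            (self.table["phase"] == phase)
            & (self.table["aoi_name"] == aoi)
            & (self.table["metric"] == metric)
        ]
        if rows.empty:
            return None
        return float(rows["mean"].iloc[0]), float(rows["dispersion"].iloc[0])


@dataclass(frozen=True)
class AlertEvent:
    """One raised alert for one monitoring window."""

    window: tuple
    kind: str  # attention_deviation | track_loss | pupil_constriction
    metric: str
    observed: float
    baseline: float
    threshold: float
    severity: float


def _phase_metrics(recording, scheme, phases, detect_kwargs):
    fixations = detect_fixations_ivt(recording, **detect_kwargs)
    out = {}
    for ph in phases:
        out[ph.name] = percent_metrics(
            fixations, scheme, (ph.start_ms, ph.end_ms)
        )
    return out


def build_baseline(
    expert_phase_metrics,
    phases,
    metrics: tuple = ("pct_duration", "pct_count"),
    dispersion_floor: float = 10.0,
    expected_valid_fraction: float = 0.95,
    source=None,
) -> BaselineProfile:
    """Aggregate per-phase AOI metrics of >= 1 expert into a baseline.

    ``expert_phase_metrics`` is a list (one entry per expert recording) of
    dicts mapping phase name to an AOI-metrics table.  Dispersion is the
    across-expert sample sd, floored at ``dispersion_floor``; with a single
    recording it is the floor itself.
    """
    if not expert_phase_metrics:
        raise ValueError("need at least one expert recording")
    if not phases:
        raise ValueError("need at least one phase")
    rows = []
    for ph in phases:
        tables = [m[ph.name] for m in expert_phase_metrics]
        aois = tables[0]["aoi_name"].tolist()
        for aoi in aois:
            for metric in metrics:
                vals = np.array(
                    [
                        float(t.loc[t["aoi_name"] == aoi, metric].iloc[0])
                        for t in tables
                    ]
                )
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    continue
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
                rows.append(
                    {
                        "phase": ph.name,
                        "aoi_name": aoi,
                        "metric": metric,
                        "mean": float(np.mean(vals)),
                        "dispersion": max(sd, dispersion_floor),
                    }
                )
    return BaselineProfile(
        phases=list(phases),
        table=pd.DataFrame(rows),
        expected_valid_fraction=expected_valid_fraction,
        dispersion_floor=dispersion_floor,
        source=list(source or []),
    )


def baseline_from_recordings(
    recordings,
    scheme: AOIScheme,
    phases,
    dispersion_floor: float = 10.0,
    source=None,
    **detect_kwargs,
) -> BaselineProfile:
    """Convenience: build a baseline directly from expert recordings."""
    detect_kwargs.setdefault("threshold_px_per_ms", DEFAULT_THRESHOLD_PX_PER_MS)
    detect_kwargs.setdefault("min_fix_ms", DEFAULT_MIN_FIX_MS)
    detect_kwargs.setdefault("max_gap_ms", DEFAULT_MAX_GAP_MS)
    per_expert = [
        _phase_metrics(rec, scheme, phases, detect_kwargs) for rec in recordings
    ]
    fracs = [
        float(
            (
                rec.samples["valid_l"].to_numpy(bool)
                | rec.samples["valid_r"].to_numpy(bool)
            ).mean()
        )
        for rec in recordings
    ]
    return build_baseline(
        per_expert,
        phases,
        dispersion_floor=dispersion_floor,
        expected_valid_fraction=float(np.mean(fracs)),
        source=source,
    )


def _rate_limit(candidates, max_alert_rate: float) -> list:
    """Keep highest-severity alerts, at most ``max_alert_rate`` per 10 min."""
    kept: list = []
    for alert in sorted(
        candidates, key=lambda a: (-a.severity, a.window[0])
    ):
        t0 = alert.window[0]
        nearby = sum(1 for k in kept if abs(k.window[0] - t0) < TEN_MINUTES_MS)
        if nearby < max_alert_rate:
            kept.append(alert)
    return sorted(kept, key=lambda a: a.window[0])


def monitor(
    recording: GazeRecording,
    scheme: AOIScheme,
    baseline: BaselineProfile,
    window_s: float = 30.0,
    step_s: float = 10.0,
    k_sigma: float = 2.0,
    min_valid_fraction: float = 0.6,
    max_alert_rate: float = 1.0,
    pupil_constriction_mm: float = -0.5,
    monitored_aois=None,
    monitored_metrics: tuple = ("pct_duration",),
    rate_limit: bool = True,
    **detect_kwargs,
) -> list:
    """Sliding-window monitoring of one recording against an expert baseline.

    Returns the time-ordered list of raised :class:`AlertEvent`; with
    ``rate_limit=False`` the pre-limit candidate list is returned instead.
    """
    if not (window_s >= step_s > 0):
        raise ValueError("need window >= step > 0")
    detect_kwargs.setdefault("threshold_px_per_ms", DEFAULT_THRESHOLD_PX_PER_MS)
    detect_kwargs.setdefault("min_fix_ms", DEFAULT_MIN_FIX_MS)
    detect_kwargs.setdefault("max_gap_ms", DEFAULT_MAX_GAP_MS)
    if monitored_aois is None:
        monitored_aois = [n for n, _ in scheme.named_aois]

    fixations = detect_fixations_ivt(recording, **detect_kwargs)
    t = recording.samples["t_ms"].to_numpy(float)
    valid = (
        recording.samples["valid_l"].to_numpy(bool)
        | recording.samples["valid_r"].to_numpy(bool)
    )
    try:
        pupil_trace = _pupil.pupillogram(recording)
    except ValueError:
        pupil_trace = None
        logger.warning("no usable pupil data; pupil alerts disabled")

    window_ms = window_s * 1000.0
    step_ms = step_s * 1000.0
    candidates = []
    start = t[0]
    while start + window_ms <= t[-1] + 1e-9:
        end = start + window_ms
        phase = next(
            (
                p.name
                for p in baseline.phases
                if p.start_ms <= start and end <= p.end_ms
            ),
            None,
        )
        if phase is None:
            logger.warning(
                "window [%.0f, %.0f) ms spans no single baseline phase; skipped",
                start,
                end,
            )
            start += step_ms
            continue
        sel = (t >= start) & (t < end)
        vf = float(valid[sel].mean()) if sel.any() else 0.0
        if vf < min_valid_fraction:
            candidates.append(
                AlertEvent(
                    window=(start, end),
                    kind="track_loss",
                    metric="valid_fraction",
                    observed=vf,
                    baseline=baseline.expected_valid_fraction,
                    threshold=min_valid_fraction,
                    severity=3.0 + (min_valid_fraction - vf),
                )
            )
        else:
            metrics = percent_metrics(fixations, scheme, (start, end))
            for aoi in monitored_aois:
                row = metrics[metrics["aoi_name"] == aoi]
                for metric in monitored_metrics:
                    expected = baseline.lookup(phase, aoi, metric)
                    if expected is None or row.empty:
                        continue
                    mean, disp = expected
                    observed = float(row[metric].iloc[0])
                    if not np.isfinite(observed):
                        continue
                    cutoff = mean - k_sigma * disp
                    if observed < cutoff:
                        deficit_sigmas = (mean - observed) / disp
                        candidates.append(
                            AlertEvent(
                                window=(start, end),
                                kind="attention_deviation",
                                metric=f"{aoi}:{metric}",
                                observed=observed,
                                baseline=mean,
                                threshold=cutoff,
                                severity=2.0 + (deficit_sigmas - k_sigma),
                            )
                        )
            if pupil_trace is not None:
                psel = (pupil_trace.t_ms >= start) & (pupil_trace.t_ms < end)
                pd_vals = pupil_trace.d[psel]
                pd_vals = pd_vals[np.isfinite(pd_vals)]
                if pd_vals.size:
                    level = float(np.mean(pd_vals))
                    if level < pupil_constriction_mm:
                        candidates.append(
                            AlertEvent(
                                window=(start, end),
                                kind="pupil_constriction",
                                metric="baselined_pupil_mm",
                                observed=level,
                                baseline=0.0,
                                threshold=pupil_constriction_mm,
                                severity=1.0 + (pupil_constriction_mm - level),
                            )
                        )
        start += step_ms
    if not rate_limit:
        return sorted(candidates, key=lambda a: a.window[0])
    return _rate_limit(candidates, max_alert_rate)
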