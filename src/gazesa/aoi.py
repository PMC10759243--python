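"""Area-of-interest assignment and percent-fixation metrics.

A fixation belongs to the unique named AOI whose half-open rectangle
contains its centroid, otherwise to the complement region (the display
"less the other AOIs").  The two attention metrics are

* percent fixation duration — a region's share of total fixation time in a
  time window, and
* percent fixation count — its share of the number of fixations,

with denominators taken over *all* regions (the whole display treated as an
AOI), so the percents across the partition sum to 100 whenever the window
contains at least one fixation.

Window clipping: a fixation contributes duration equal to its overlap with
the window, and counts toward fixation_count iff its onset lies in the
window (half-open ``[start, end)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixation import Fixation
from .io import AOIScheme

logger = logging.getLogger(__name__)

#: anomaly interval of the default monitoring scenario: 2:00-2:50
CRITICAL_WINDOW_MS = (120_000.0, 170_000.0)

METRICS_COLUMNS = [
    "participant_id",
    "aoi_name",
    "window_start_ms",
    "window_end_ms",
    "fixation_count",
    "total_duration_ms",
    "pct_duration",
    "pct_count",
]


def assign_aoi(fixation: Fixation, scheme: AOIScheme) -> str:
    """Name of the region containing the fixation centroid.

    Half-open rectangles make membership unique; centroids outside the
    screen fall back to the complement region with a logged warning.
    """
    x, y = fixation.cx, fixation.cy
    if not (0 <= x < scheme.screen_w and 0 <= y < scheme.screen_h):
        logger.warning(
            "fixation centroid (%.1f, %.1f) outside screen; assigned to %s",
            x,
            y,
            scheme.complement_name,
        )
        return scheme.complement_name
    for name, (x0, y0, x1, y1) in scheme.named_aois:
        if x0 <= x < x1 and y0 <= y < y1:
            return name
    return scheme.complement_name


def percent_metrics(
    fixations,
    scheme: AOIScheme,
    window: tuple | None = None,
    participant_id: str = "",
) -> pd.DataFrame:
    """Per-region fixation metrics within a time window.

    Returns one row per region (complement first).  With zero fixations in
    the window, counts are 0 and percents are NaN (flagged, not silently 0).
    """
    if window is None:
        if fixations:
            window = (
                min(f.onset_ms for f in fixations),
                max(f.offset_ms for f in fixations) + 1e-9,
            )
        else:
            window = (0.0, 1.0)
    start, end = window
    if not start < end:
        raise ValueError("window start must precede end")

    dur = {name: 0.0 for name in scheme.region_names}
    cnt = {name: 0 for name in scheme.region_names}
    for f in fixations:
        overlap = min(f.offset_ms, end) - max(f.onset_ms, start)
        region = assign_aoi(f, scheme)
        if overlap > 0:
            dur[region] += overlap
        if start <= f.onset_ms < end:
            cnt[region] += 1
    total_dur = sum(dur.values())
    total_cnt = sum(cnt.values())
    if total_cnt == 0 and total_dur == 0:
        logger.warning("window [%s, %s) ms contains no fixations", start, end)

    rows = []
    for name in scheme.region_names:
        rows.append(
            {
                "participant_id": participant_id,
                "aoi_name": name,
                "window_start_ms": start,
                "window_end_ms": end,
                "fixation_count": cnt[name],
                "total_duration_ms": dur[name],
                "pct_duration": (
                    100.0 * dur[name] / total_dur if total_dur > 0 else np.nan
                ),
                "pct_count": (
                    100.0 * cnt[name] / total_cnt if total_cnt > 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def critical_window_report(
    fixations,
    scheme: AOIScheme,
    window: tuple = CRITICAL_WINDOW_MS,
    participant_id: str = "",
) -> pd.DataFrame:
    """Percent metrics restricted to the critical (anomaly) interval."""
    return percent_metrics(fixations, scheme, window, participant_id)


@dataclass
class ScanPath:
    """Time-ordered fixation sequence with connecting saccade segments.

    ``nodes`` has one row per fixation (index, cx, cy, duration_ms,
    aoi_name); ``saccades`` one row per transition, with duration equal to
    the gap between the previous offset and the next onset.
    """

    nodes: pd.DataFrame
    saccades: pd.DataFrame

    def __len__(self) -> int:
        return len(self.nodes)


def build_scanpath(fixations, scheme: AOIScheme) -> ScanPath:
    """Construct the scanpath of a time-ordered fixation list."""
    onsets = [f.onset_ms for f in fixations]
    if onsets != sorted(onsets):
        raise ValueError("fixations must be time-ordered")
    nodes = pd.DataFrame(
        [
            {
                "index": f.index,
                "cx": f.cx,
                "cy": f.cy,
                "duration_ms": f.duration_ms,
                "aoi_name": assign_aoi(f, scheme),
            }
            for f in fixations
        ],
        columns=["index", "cx", "cy", "duration_ms", "aoi_name"],
    )
    saccades = pd.DataFrame(
        [
            {
                "from_index": a.index,
                "to_index": b.index,
                "duration_ms": b.onset_ms - a.offset_ms,
            }
            for a, b in zip(fixations[:-1], fixations[1:])
        ],
        columns=["from_index", "to_index", "duration_ms"],
    )
    return ScanPath(nodes=nodes, saccades=saccades)
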