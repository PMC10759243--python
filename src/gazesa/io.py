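"""Reading and writing of gaze-analysis artifacts.

Raw gaze streams arrive as delimited text tables in whatever column layout a
screen-mounted eye tracker exports; a :class:`Dialect` maps physical column
names (and missing-value sentinels) onto the logical schema used throughout
the package:

    t_ms, x, y, pupil_l, pupil_r, valid_l, valid_r

Coordinates are screen pixels with the origin at the top-left corner and y
increasing downward.  Timestamps are milliseconds from recording start.
Areas of interest (AOIs) are axis-aligned rectangles, half-open on the right
and bottom edges, so every screen point belongs to at most one named AOI; the
remainder of the display is the implicit complement region (by convention
"AOI I").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: logical column order of a gaze table
GAZE_COLUMNS = ["t_ms", "x", "y", "pupil_l", "pupil_r", "valid_l", "valid_r"]


class GazeFormatError(ValueError):
    """A file does not conform to the expected table layout."""


class GazeValidationError(ValueError):
    """A parsed artifact violates a domain invariant."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping for one tracker export format.

    Parameters
    ----------
    columns
        Map from logical column name to the physical header in the file.
    sep
        Field delimiter ("\\t" for TSV exports, "," for CSV).
    time_scale_ms
        Multiplier converting the file's time unit to milliseconds
        (1.0 for ms, 1e-3 for device microseconds).
    pupil_missing_sentinels
        Physical pupil values to treat as missing (some exports use -1 or 0).
    """

    columns: dict = field(
        default_factory=lambda: {c: c for c in GAZE_COLUMNS}
    )
    sep: str = "\t"
    time_scale_ms: float = 1.0
    pupil_missing_sentinels: tuple = (-1.0,)


DEFAULT_DIALECT = Dialect()


@dataclass
class GazeRecording:
    """A time-ordered raw gaze sample stream.

    ``samples`` holds one row per sample with the logical columns of
    :data:`GAZE_COLUMNS`; invalid eyes carry NaN gaze/pupil values and a
    False validity flag.
    """

    samples: pd.DataFrame
    rate_hz: float
    screen_w: int
    screen_h: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.samples
        missing = [c for c in GAZE_COLUMNS if c not in df.columns]
        if missing:
            raise GazeFormatError(f"gaze table missing columns: {missing}")
        t = df["t_ms"].to_numpy(float)
        if len(t) and t[0] < 0:
            raise GazeValidationError("timestamps must be >= 0")
        if len(t) > 1:
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                raise GazeValidationError(
                    f"timestamps not strictly increasing at row {bad[0] + 1} "
                    f"(t={t[bad[0] + 1]!r} after t={t[bad[0]]!r})"
                )
            if self.rate_hz <= 0:
                raise GazeValidationError("rate_hz must be positive")
            median_dt = float(np.median(np.diff(t)))
            nominal_dt = 1000.0 / self.rate_hz
            if median_dt > 0 and abs(median_dt - nominal_dt) > 0.1 * nominal_dt:
                raise GazeValidationError(
                    f"declared rate {self.rate_hz} Hz inconsistent with median "
                    f"inter-sample interval {median_dt:.3f} ms"
                )
        for col in ("pupil_l", "pupil_r"):
            d = df[col].to_numpy(float)
            present = np.isfinite(d)
            if np.any((d[present] <= 0) | (d[present] >= 10)):
                raise GazeValidationError(
                    f"{col} values outside the physiological range (0, 10) mm"
                )
        either_valid = df["valid_l"].to_numpy(bool) | df["valid_r"].to_numpy(bool)
        xy = df[["x", "y"]].to_numpy(float)
        if np.any(~np.isfinite(xy[either_valid])):
            raise GazeValidationError("non-finite gaze position on a valid sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_ms(self) -> float:
        t = self.samples["t_ms"].to_numpy(float)
        return float(t[-1] - t[0]) if len(t) > 1 else 0.0

    def equals(self, other: "GazeRecording", atol: float = 1e-9) -> bool:
        """Field-for-field equality up to ``atol`` on numeric columns."""
        if (self.rate_hz, self.screen_w, self.screen_h) != (
            other.rate_hz,
            other.screen_w,
            other.screen_h,
        ) or len(self.samples) != len(other.samples):
            return False
        for c in GAZE_COLUMNS:
            a = self.samples[c].to_numpy()
            b = other.samples[c].to_numpy()
            if c.startswith("valid"):
                if not np.array_equal(a.astype(bool), b.astype(bool)):
                    return False
            else:
                a = a.astype(float)
                b = b.astype(float)
                same = np.isclose(a, b, atol=atol) | (np.isnan(a) & np.isnan(b))
                if not same.all():
                    return False
        return True


@dataclass
class AOIScheme:
    """A partition of the screen into named rectangles plus a complement.

    Rectangles are ``(x0, y0, x1, y1)`` in screen pixels and half-open:
    a point (x, y) lies in a rectangle iff x0 <= x < x1 and y0 <= y < y1.
    """

    named_aois: list
    screen_w: int
    screen_h: int
    complement_name: str = "AOI I"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [n for n, _ in self.named_aois]
        if len(set(names)) != len(names):
            raise GazeValidationError(f"duplicate AOI names: {names}")
        if self.complement_name in names:
            raise GazeValidationError(
                f"complement name {self.complement_name!r} clashes with a named AOI"
            )
        for name, (x0, y0, x1, y1) in self.named_aois:
            if not (x0 < x1 and y0 < y1):
                raise GazeValidationError(f"AOI {name!r} has an empty rectangle")
            if x0 < 0 or y0 < 0 or x1 > self.screen_w or y1 > self.screen_h:
                raise GazeValidationError(
                    f"AOI {name!r} extends outside the {self.screen_w}x"
                    f"{self.screen_h} screen"
                )
        for i, (na, ra) in enumerate(self.named_aois):
            for nb, rb in self.named_aois[i + 1 :]:
                if ra[0] < rb[2] and rb[0] < ra[2] and ra[1] < rb[3] and rb[1] < ra[3]:
                    raise GazeValidationError(f"AOIs {na!r} and {nb!r} overlap")

    @property
    def region_names(self) -> list:
        """Complement region first, then named AOIs in declared order."""
        return [self.complement_name] + [n for n, _ in self.named_aois]


# ---------------------------------------------------------------------------
# raw gaze tables


def read_gaze_table(
    path,
    dialect: Dialect = DEFAULT_DIALECT,
    rate_hz: float | None = None,
    screen: tuple | None = None,
) -> GazeRecording:
    """Read a delimited gaze export into a validated :class:`GazeRecording`.

    Rows whose timestamp fails to parse are dropped with a logged count.
    ``rate_hz`` defaults to the value implied by the median inter-sample
    interval; ``screen`` defaults to the bounding box of observed gaze.
    """
    raw = pd.read_csv(path, sep=dialect.sep)
    for logical, physical in dialect.columns.items():
        if physical not in raw.columns:
            raise GazeFormatError(
                f"missing mandatory column {physical!r} (logical {logical!r})"
            )
    df = pd.DataFrame(
        {logical: raw[physical] for logical, physical in dialect.columns.items()}
    )
    t = pd.to_numeric(df["t_ms"], errors="coerce") * dialect.time_scale_ms
    n_bad = int(t.isna().sum())
    if n_bad:
        logger.warning("dropped %d rows with unparseable timestamps", n_bad)
    df = df[t.notna()].reset_index(drop=True)
    df["t_ms"] = t.dropna().to_numpy(float)
    for col in ("x", "y", "pupil_l", "pupil_r"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    for col in ("pupil_l", "pupil_r"):
        vals = df[col].to_numpy()
        for sentinel in dialect.pupil_missing_sentinels:
            vals[vals == sentinel] = np.nan
        df[col] = vals
    for col in ("valid_l", "valid_r"):
        df[col] = (
            df[col]
            .map(lambda v: str(v).strip().lower() in ("1", "true", "1.0", "yes"))
            .astype(bool)
        )
    # an eye without a pupil reading did not track that sample
    df.loc[df["pupil_l"].isna(), "valid_l"] = False
    df.loc[df["pupil_r"].isna(), "valid_r"] = False

    if rate_hz is None:
        dt = np.diff(df["t_ms"].to_numpy(float))
        if len(dt) == 0 or np.median(dt) <= 0:
            raise GazeValidationError("cannot infer sampling rate from < 2 samples")
        rate_hz = 1000.0 / float(np.median(dt))
    if screen is None:
        w = int(np.ceil(np.nanmax(df["x"].to_numpy(float), initial=1.0)))
        h = int(np.ceil(np.nanmax(df["y"].to_numpy(float), initial=1.0)))
        screen = (max(w, 1), max(h, 1))
    return GazeRecording(df[GAZE_COLUMNS], rate_hz, screen[0], screen[1])


def write_gaze_table(
    recording: GazeRecording, path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    """Write a recording in the given dialect (logical names by default)."""
    out = recording.samples.copy()
    out["t_ms"] = out["t_ms"] / dialect.time_scale_ms
    for col in ("valid_l", "valid_r"):
        out[col] = out[col].astype(int)
    out.columns = [dialect.columns[c] for c in GAZE_COLUMNS]
    out.to_csv(path, sep=dialect.sep, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# AOI configs


def read_aoi_config(path, screen: tuple | None = None) -> AOIScheme:
    """Read an AOI scheme from a YAML (or JSON) config file.

    Expected keys: ``screen: {w, h}``, ``aois: [{name, x0, y0, x1, y1}, ...]``,
    optional ``complement_name``.  ``screen`` as an argument overrides the file.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not cfg.get("aois"):
        raise GazeFormatError("AOI config declares no rectangles")
    if screen is None:
        try:
            screen = (cfg["screen"]["w"], cfg["screen"]["h"])
        except (KeyError, TypeError) as exc:
            raise GazeFormatError("AOI config missing screen {w, h}") from exc
    named = [
        (a["name"], (float(a["x0"]), float(a["y0"]), float(a["x1"]), float(a["y1"])))
        for a in cfg["aois"]
    ]
    return AOIScheme(
        named_aois=named,
        screen_w=screen[0],
        screen_h=screen[1],
        complement_name=cfg.get("complement_name", "AOI I"),
    )


def write_aoi_config(scheme: AOIScheme, path) -> None:
    cfg = {
        "screen": {"w": scheme.screen_w, "h": scheme.screen_h},
        "complement_name": scheme.complement_name,
        "aois": [
            {"name": n, "x0": r[0], "y0": r[1], "x1": r[2], "y1": r[3]}
            for n, r in scheme.named_aois
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# result tables (fixations, AOI metrics, pairwise comparisons)

FIXATION_COLUMNS = ["index", "onset_ms", "offset_ms", "duration_ms", "cx", "cy"]
COMPARISON_COLUMNS = [
    "pair",
    "test_statistic",
    "std_error",
    "std_test_statistic",
    "sig",
    "adj_sig",
]


def write_fixation_table(fixations, path) -> None:
    """Write detected fixations as a headered TSV (3-decimal precision)."""
    rows = [
        {
            "index": f.index,
            "onset_ms": f.onset_ms,
            "offset_ms": f.offset_ms,
            "duration_ms": f.duration_ms,
            "cx": f.cx,
            "cy": f.cy,
        }
        for f in fixations
    ]
    df = pd.DataFrame(rows, columns=FIXATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_fixation_table(path) -> list:
    from .fixation import Fixation

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"fixation table missing columns: {missing}")
    return [
        Fixation(
            index=int(r["index"]),
            onset_ms=float(r["onset_ms"]),
            offset_ms=float(r["offset_ms"]),
            cx=float(r["cx"]),
            cy=float(r["cy"]),
        )
        for _, r in df.iterrows()
    ]


def write_metrics_table(rows: pd.DataFrame, path) -> None:
    """Write an AOI metrics table (one row per participant/AOI/window)."""
    rows.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_comparison_table(rows, path) -> None:
    """Write pairwise post-hoc comparisons.

    Columns mirror the conventional rank-based post-hoc report: pair,
    test_statistic (mean-rank difference), std_error, std_test_statistic,
    sig (raw p), adj_sig (multiplicity-adjusted p), all at 3 decimals.
    """
    recs = []
    for c in rows:
        recs.append(
            {
                "pair": f"{c.pair[0]} - {c.pair[1]}",
                "test_statistic": c.rank_diff,
                "std_error": c.se,
                "std_test_statistic": c.z,
                "sig": c.p,
                "adj_sig": c.p_adj,
            }
        )
    df = pd.DataFrame(recs, columns=COMPARISON_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_comparison_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COMPARISON_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"comparison table missing columns: {missing}")
    return df
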