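"""Synthetic gaze-recording generator.

Emulates a screen-mounted 300 Hz eye-tracker recording of a five-minute
real-time monitoring scenario: an operator watches a dynamically updating
display partitioned into a complement region ("AOI I", the full display
less the named AOIs) and two named indicator regions ("AOI II", "AOI III"),
with an anomaly present from 2:00 to 2:50 that competent monitoring should
pick up through the AOI III indicators.

Gaze is generated as an alternating fixation/saccade event stream: each
fixation targets a region drawn from the active phase's attention-weight
map, sits at a uniform point inside that region with small Gaussian
per-sample jitter, and lasts a lognormal duration; saccades are short
constant-velocity segments between fixation centres.  Blinks are
Poisson-scheduled spans during which both eyes lose tracking (gaze and
pupil missing).  Pupil diameter is a shared latent signal — baseline plus
a smooth dilation bump responding to the anomaly — observed per eye with
independent Gaussian noise, so binocular averaging demonstrably reduces
noise.

Two behaviour profiles encode the qualitative expert/novice contrast:
identical attention before the anomaly; during it the expert shifts
attention weight strongly onto AOI III with a pronounced pupil dilation,
while the novice stays on the complement region with a damped response.
All distributional constants are invented, documented stand-ins chosen to
reproduce the contrast in direction, not magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AOIScheme, GazeRecording, GAZE_COLUMNS

IVT_THRESHOLD = 0.42  # px/ms; generator jitter must stay safely below this


class ConfigurationError(ValueError):
    """Profile/scenario combination cannot produce well-posed samples."""


#: attention weights shared by both profiles outside the anomaly
_BASE_WEIGHTS = {"AOI I": 0.55, "AOI II": 0.25, "AOI III": 0.20}


@dataclass(frozen=True)
class BehaviorProfile:
    """Generative parameters of one participant type.

    ``phase_schedule`` is a list of ``(start_s, end_s, weights)`` with
    AOI-attention weights summing to 1 per phase.  Fixation durations are
    lognormal (median ``fix_median_ms``, log-sd ``fix_sigma``); jitter is
    the per-sample Gaussian positional sd inside a fixation.
    """

    label: str
    phase_schedule: tuple
    fix_median_ms: float = 300.0
    fix_sigma: float = 0.4
    fix_min_ms: float = 100.0
    jitter_sd_px: float = 0.25
    saccade_ms: tuple = (20.0, 60.0)
    min_saccade_px: float = 40.0
    blink_rate_per_min: float = 15.0
    blink_ms: tuple = (100.0, 300.0)
    pupil_baseline_mm: float = 3.0
    dilation_mm: float = 0.4
    response_lag_s: float = 2.0
    pupil_noise_sd_mm: float = 0.05

    def __post_init__(self) -> None:
        for start_s, end_s, weights in self.phase_schedule:
            if not start_s < end_s:
                raise ConfigurationError("phase start must precede end")
            vals = np.array(list(weights.values()), float)
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"phase [{start_s}, {end_s}) weights must be nonnegative "
                    "and sum to 1"
                )

    def weights_at(self, t_ms: float) -> dict:
        for start_s, end_s, weights in self.phase_schedule:
            if start_s * 1000.0 <= t_ms < end_s * 1000.0:
                return weights
        return self.phase_schedule[-1][2]


def default_aoi_scheme(screen: tuple = (1920, 1080)) -> AOIScheme:
    """Stand-in AOI geometry for the default monitoring scenario.

    Synthetic: two named indicator rectangles on the right half of a
    1920x1080 display, the rest of the screen forming the complement.
    """
    return AOIScheme(
        named_aois=[
            ("AOI II", (960.0, 60.0, 1350.0, 520.0)),
            ("AOI III", (1400.0, 60.0, 1860.0, 700.0)),
        ],
        screen_w=screen[0],
        screen_h=screen[1],
        complement_name="AOI I",
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """The default monitoring scenario: 5 minutes at 300 Hz, anomaly 2:00-2:50."""

    duration_s: float = 300.0
    rate_hz: float = 300.0
    screen: tuple = (1920, 1080)
    anomaly_s: tuple = (120.0, 170.0)
    n_novices: int = 23
    n_experts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigurationError("rate and duration must be positive")
        if not 0 <= self.anomaly_s[0] < self.anomaly_s[1] <= self.duration_s:
            raise ConfigurationError("anomaly window must lie within the scenario")

    @property
    def scheme(self) -> AOIScheme:
        return default_aoi_scheme(self.screen)


def default_profiles(
    scenario: ScenarioConfig | None = None,
) -> tuple:
    """The (expert, novice) behaviour profiles of the default scenario.

    Pre- and post-anomaly phases are identical across profiles; the entire
    contrast is the anomaly-phase attention map and the pupil response.
    """
    sc = scenario or ScenarioConfig()
    a0, a1 = sc.anomaly_s
    end = sc.duration_s
    expert_anom = {"AOI I": 0.10, "AOI II": 0.20, "AOI III": 0.70}
    novice_anom = {"AOI I": 0.70, "AOI II": 0.20, "AOI III": 0.10}
    expert = BehaviorProfile(
        label="expert",
        phase_schedule=(
            (0.0, a0, _BASE_WEIGHTS),
            (a0, a1, expert_anom),
            (a1, end, _BASE_WEIGHTS),
        ),
        dilation_mm=0.4,
    )
    novice = BehaviorProfile(
        label="novice",
        phase_schedule=(
            (0.0, a0, _BASE_WEIGHTS),
            (a0, a1, novice_anom),
            (a1, end, _BASE_WEIGHTS),
        ),
        dilation_mm=0.15,
    )
    return expert, novice


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    ``fixations``/``saccades`` partition the recording span (blinks overlay
    them as track-loss spans); ``pupil_latent`` is the shared noise-free
    pupil signal on the sample grid.
    """

    fixations: pd.DataFrame  # onset_ms, offset_ms, cx, cy, region
    saccades: pd.DataFrame  # start_ms, end_ms
    blinks: pd.DataFrame  # start_ms, end_ms
    pupil_latent: np.ndarray
    pupil_baseline_mm: float
    dilation_mm: float
    dilation_peak_ms: float

    def occupancy(self, window_ms: tuple) -> dict:
        """True per-region fixation time (ms) within a window."""
        out: dict = {}
        for row in self.fixations.itertuples():
            overlap = min(row.offset_ms, window_ms[1]) - max(
                row.onset_ms, window_ms[0]
            )
            if overlap > 0:
                out[row.region] = out.get(row.region, 0.0) + overlap
        return out


def _sample_point_in_region(rng, region: str, scheme: AOIScheme):
    if region != scheme.complement_name:
        rect = dict(scheme.named_aois)[region]
        return (
            rng.uniform(rect[0], rect[2]),
            rng.uniform(rect[1], rect[3]),
        )
    # complement: rejection-sample a screen point outside every named AOI
    for _ in range(10_000):
        x = rng.uniform(0, scheme.screen_w)
        y = rng.uniform(0, scheme.screen_h)
        if not any(
            r[0] <= x < r[2] and r[1] <= y < r[3] for _, r in scheme.named_aois
        ):
            return x, y
    raise ConfigurationError("named AOIs leave no complement area to sample")


def _dilation_bump(t_ms: np.ndarray, scenario: ScenarioConfig, lag_s: float):
    """Raised-cosine dilation response over the (lagged) anomaly window."""
    a = (scenario.anomaly_s[0] + lag_s) * 1000.0
    b = (scenario.anomaly_s[1] + lag_s) * 1000.0
    u = (t_ms - a) / (b - a)
    bump = np.where((u >= 0) & (u <= 1), 0.5 * (1 - np.cos(2 * np.pi * u)), 0.0)
    return bump, 0.5 * (a + b)


def simulate_recording(
    profile: BehaviorProfile,
    scenario: ScenarioConfig | None = None,
    seed: int = 0,
    scheme: AOIScheme | None = None,
) -> tuple:
    """Simulate one recording; returns ``(GazeRecording, GroundTruth)``.

    Fully reproducible from ``seed``.
    """
    sc = scenario or ScenarioConfig()
    scheme = scheme or sc.scheme
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sc.rate_hz
    if profile.jitter_sd_px > IVT_THRESHOLD * dt / 4.0:
        raise ConfigurationError(
            f"jitter sd {profile.jitter_sd_px} px too large for the "
            f"{IVT_THRESHOLD} px/ms threshold at {sc.rate_hz} Hz"
        )
    duration_ms = sc.duration_s * 1000.0
    n = int(round(sc.duration_s * sc.rate_hz))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)

    mu = np.log(profile.fix_median_ms)
    fix_rows, sac_rows = [], []
    cur = 0.0
    prev_center = None
    while cur < duration_ms:
        if prev_center is not None:
            sac_dur = rng.uniform(*profile.saccade_ms)
        else:
            sac_dur = 0.0
        fix_start = cur + sac_dur
        region = profile.weights_at(min(fix_start, duration_ms - 1e-9))
        names = list(region.keys())
        probs = np.array([region[k] for k in names])
        chosen = names[rng.choice(len(names), p=probs)]
        for _ in range(100):
            center = _sample_point_in_region(rng, chosen, scheme)
            if prev_center is None:
                break
            d = np.hypot(center[0] - prev_center[0], center[1] - prev_center[1])
            if d >= profile.min_saccade_px:
                break
        fix_dur = max(
            profile.fix_min_ms, float(rng.lognormal(mu, profile.fix_sigma))
        )
        fix_end = min(fix_start + fix_dur, duration_ms)
        if prev_center is not None:
            sac_end = min(fix_start, duration_ms)
            sac_rows.append(
                {
                    "start_ms": cur,
                    "end_ms": sac_end,
                    "x0": prev_center[0],
                    "y0": prev_center[1],
                    "x1": center[0],
                    "y1": center[1],
                }
            )
            i0, i1 = np.searchsorted(t, (cur, sac_end))
            if i1 > i0 and sac_end > cur:
                frac = (t[i0:i1] - cur) / (sac_end - cur)
                x[i0:i1] = prev_center[0] + frac * (center[0] - prev_center[0])
                y[i0:i1] = prev_center[1] + frac * (center[1] - prev_center[1])
        if fix_end > fix_start:
            fix_rows.append(
                {
                    "onset_ms": fix_start,
                    "offset_ms": fix_end,
                    "cx": center[0],
                    "cy": center[1],
                    "region": chosen,
                }
            )
            i0, i1 = np.searchsorted(t, (fix_start, fix_end))
            m = i1 - i0
            x[i0:i1] = center[0] + rng.normal(0, profile.jitter_sd_px, m)
            y[i0:i1] = center[1] + rng.normal(0, profile.jitter_sd_px, m)
        prev_center = center
        cur = fix_end

    # blinks: Poisson-scheduled track loss in both gaze and pupil channels
    n_blinks = rng.poisson(profile.blink_rate_per_min * sc.duration_s / 60.0)
    starts = np.sort(rng.uniform(0, duration_ms, n_blinks))
    durs = rng.uniform(*profile.blink_ms, n_blinks)
    valid = np.ones(n, bool)
    blink_rows = []
    for s, d in zip(starts, durs):
        e = min(s + d, duration_ms)
        blink_rows.append({"start_ms": s, "end_ms": e})
        i0, i1 = np.searchsorted(t, (s, e))
        valid[i0:i1] = False

    bump, peak_ms = _dilation_bump(t, sc, profile.response_lag_s)
    latent = profile.pupil_baseline_mm + profile.dilation_mm * bump
    pupil_l = latent + rng.normal(0, profile.pupil_noise_sd_mm, n)
    pupil_r = latent + rng.normal(0, profile.pupil_noise_sd_mm, n)
    np.clip(pupil_l, 0.5, 9.5, out=pupil_l)
    np.clip(pupil_r, 0.5, 9.5, out=pupil_r)

    x[~valid] = np.nan
    y[~valid] = np.nan
    pupil_l[~valid] = np.nan
    pupil_r[~valid] = np.nan

    samples = pd.DataFrame(
        {
            "t_ms": t,
            "x": x,
            "y": y,
            "pupil_l": pupil_l,
            "pupil_r": pupil_r,
            "valid_l": valid,
            "valid_r": valid.copy(),
        }
    )[GAZE_COLUMNS]
    recording = GazeRecording(samples, sc.rate_hz, sc.screen[0], sc.screen[1])
    truth = GroundTruth(
        fixations=pd.DataFrame(
            fix_rows, columns=["onset_ms", "offset_ms", "cx", "cy", "region"]
        ),
        saccades=pd.DataFrame(
            sac_rows, columns=["start_ms", "end_ms", "x0", "y0", "x1", "y1"]
        ),
        blinks=pd.DataFrame(blink_rows, columns=["start_ms", "end_ms"]),
        pupil_latent=latent,
        pupil_baseline_mm=profile.pupil_baseline_mm,
        dilation_mm=profile.dilation_mm,
        dilation_peak_ms=peak_ms,
    )
    return recording, truth


def _perturb_novice(profile: BehaviorProfile, rng) -> BehaviorProfile:
    """Per-participant jitter around the novice profile.

    Attention weights get Dirichlet noise centred on the phase map; pupil
    baseline and dilation amplitude vary mildly across participants.
    """
    schedule = []
    for start_s, end_s, weights in profile.phase_schedule:
        names = list(weights.keys())
        alpha = np.maximum(np.array([weights[k] for k in names]) * 80.0, 1e-3)
        w = rng.dirichlet(alpha)
        schedule.append((start_s, end_s, dict(zip(names, w))))
    return replace(
        profile,
        phase_schedule=tuple(schedule),
        pupil_baseline_mm=float(
            np.clip(profile.pupil_baseline_mm + rng.normal(0, 0.15), 2.0, 6.0)
        ),
        dilation_mm=float(
            np.clip(profile.dilation_mm * rng.uniform(0.8, 1.2), 0.0, 2.0)
        ),
    )


@dataclass
class CohortMember:
    participant_id: str
    label: str
    seed: int
    recording: GazeRecording
    truth: GroundTruth


def simulate_cohort(scenario: ScenarioConfig | None = None) -> tuple:
    """Simulate the full cohort: novices with per-participant jitter + expert(s).

    Returns ``(members, manifest)`` where the manifest maps participant id to
    profile label and derived seed.  All derived seeds are distinct.
    """
    sc = scenario or ScenarioConfig()
    expert, novice = default_profiles(sc)
    ss = np.random.SeedSequence(sc.seed)
    n_total = sc.n_novices + sc.n_experts
    children = ss.spawn(n_total)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    # resolve (vanishingly unlikely) collisions to keep seeds distinct
    while len(set(seeds)) != len(seeds):
        seen, fixed = set(), []
        for s in seeds:
            while s in seen:
                s = (s + 1) % (2**31)
            seen.add(s)
            fixed.append(s)
        seeds = fixed

    members = []
    perturb_rng = np.random.default_rng(ss.spawn(1)[0])
    for i in range(sc.n_experts):
        pid = f"expert_{i + 1:02d}"
        rec, truth = simulate_recording(expert, sc, seed=seeds[i])
        members.append(CohortMember(pid, "expert", seeds[i], rec, truth))
    for j in range(sc.n_novices):
        pid = f"novice_{j + 1:02d}"
        seed = seeds[sc.n_experts + j]
        prof = _perturb_novice(novice, perturb_rng)
        rec, truth = simulate_recording(prof, sc, seed=seed)
        members.append(CohortMember(pid, "novice", seed, rec, truth))
    manifest = pd.DataFrame(
        [
            {"participant_id": m.participant_id, "profile": m.label, "seed": m.seed}
            for m in members
        ]
    )
    return members, manifest


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize ground truth as JSON (latent pupil summarized by its params)."""
    payload = {
        "fixations": truth.fixations.to_dict(orient="records"),
        "saccades": truth.saccades.to_dict(orient="records"),
        "blinks": truth.blinks.to_dict(orient="records"),
        "pupil_baseline_mm": truth.pupil_baseline_mm,
        "dilation_mm": truth.dilation_mm,
        "dilation_peak_ms": truth.dilation_peak_ms,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
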