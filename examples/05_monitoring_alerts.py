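"""Expert-baseline attention monitoring with rate-limited alerts.

Builds a baseline from an expert recording, then monitors a novice of the
same scenario: the novice's missing attention on AOI III during the anomaly
raises an attention-deviation alert; the expert monitored against their own
baseline stays silent.
"""

from gazesa import (
    ScenarioConfig,
    baseline_from_recordings,
    default_profiles,
    monitor,
    scenario_phases,
    simulate_recording,
)

scenario = ScenarioConfig(duration_s=60, rate_hz=120, anomaly_s=(20, 40))
scheme = scenario.scheme
phases = scenario_phases(
    tuple(1000.0 * s for s in scenario.anomaly_s), scenario.duration_s * 1000.0
)

expert_p, novice_p = default_profiles(scenario)
expert_rec, _ = simulate_recording(expert_p, scenario, seed=8)
novice_rec, _ = simulate_recording(novice_p, scenario, seed=9)

baseline = baseline_from_recordings([expert_rec], scheme, phases)

for label, rec in (("expert", expert_rec), ("novice", novice_rec)):
    alerts = monitor(rec, scheme, baseline, window_s=20, step_s=10, k_sigma=2)
    print(f"{label}: {len(alerts)} alert(s)")
    for a in alerts:
        print(
            f"  [{a.window[0] / 1000:.0f}-{a.window[1] / 1000:.0f} s] {a.kind} "
            f"on {a.metric}: observed {a.observed:.1f} vs baseline "
            f"{a.baseline:.1f} (trigger < {a.threshold:.1f})"
        )
# An attention-deviation alert fires when a monitored AOI's percent fixation
# duration drops more than 2 dispersions below the expert baseline for that
# scenario phase; alerts are capped at one per 10 minutes.
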