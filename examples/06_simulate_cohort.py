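"""Generate a study cohort on disk: gaze tables, AOI config, ground truth.

Writes one tracker-style TSV per participant plus the scenario's AOI
configuration and per-recording ground-truth JSON under ./scratch/cohort.
"""

from pathlib import Path

from gazesa import ScenarioConfig, simulate_cohort, write_aoi_config, write_gaze_table
from gazesa.simulate import write_ground_truth

out = Path("scratch/cohort")
out.mkdir(parents=True, exist_ok=True)

scenario = ScenarioConfig(duration_s=60, rate_hz=120, anomaly_s=(20, 40), seed=17)
members, manifest = simulate_cohort(scenario)

write_aoi_config(scenario.scheme, out / "aoi_config.yaml")
for m in members:
    write_gaze_table(m.recording, out / f"{m.participant_id}.tsv")
    write_ground_truth(m.truth, out / f"{m.participant_id}_truth.json")
manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)

print(manifest.to_string(index=False))
print(f"\nwrote {len(members)} recordings to {out}/")
# The manifest maps each participant to its profile and derived seed; the
# gaze tables round-trip through gazesa.io.read_gaze_table for the full
# pipeline.
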