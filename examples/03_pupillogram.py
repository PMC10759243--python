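"""Pupillogram preprocessing: from noisy per-eye streams to dilation in mm.

Runs the full chain (gap interpolation, Savitzky-Golay smoothing, binocular
averaging, baseline adjustment, normalization) and reports the recovered
dilation response against the generator's ground truth.
"""

import numpy as np

from gazesa import ScenarioConfig, default_profiles, pupillogram, simulate_recording

scenario = ScenarioConfig(duration_s=60, rate_hz=120, anomaly_s=(20, 40))
expert, _ = default_profiles(scenario)
recording, truth = simulate_recording(expert, scenario, seed=42)

trace = pupillogram(recording, sg_window=21, sg_order=3)

peak = float(np.nanmax(trace.d))
t_peak = float(trace.t_ms[np.nanargmax(np.nan_to_num(trace.d, nan=-np.inf))])
print("pipeline stages:", " -> ".join(trace.history))
print(f"peak dilation: {peak:.3f} mm at t = {t_peak / 1000:.1f} s")
print(
    f"ground truth:  {truth.dilation_mm:.3f} mm peaking at "
    f"t = {truth.dilation_peak_ms / 1000:.1f} s"
)
print(f"peak relative change: {float(np.nanmax(trace.d_norm)) * 100:.1f} %")
# `d` is the change in pupil diameter relative to the first-5-s baseline
# (mm); `d_norm` the same change relative to the baseline diameter. The
# anomaly-driven dilation bump should be recovered close to the injected
# amplitude and time.
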