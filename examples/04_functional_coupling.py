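"""Degree of Functional Coupling: entrainment of activity to the 24-h day.

A 3-day activity window is autocorrelated and Fourier-transformed; DFC is
the share of spectral power at 24-h harmonics.  1 = perfect entrainment,
noise pushes the value toward the arrhythmic baseline.
"""

import numpy as np

from hoglog import EffectConfig, StudyConfig, dfc, generate_minutes, moving_dfc

t = np.arange(3 * 1440)
clean = 1.0 + 0.5 * np.cos(2 * np.pi * t / 1440.0)
print(f"noise-free 24-h series : DFC = {dfc(clean).dfc:.6f}")
rng = np.random.default_rng(0)
for gain in (0.2, 0.5, 1.5):
    noisy = clean + gain * rng.normal(size=t.size)
    print(f"noise gain {gain:<4}        : DFC = {dfc(noisy).dfc:.3f}")

config = StudyConfig(
    n_individuals=2, pre_days=5, festival_days=5, post_days=0, seed=5,
    effects=EffectConfig(dfc_noise_gain=0.8),
)
minutes, _, _ = generate_minutes(config)
series = minutes.rename(columns={"asd_true": "asd"})[["individual_id", "timestamp", "asd"]]
windows = moving_dfc(series)
calendar = config.calendar()
windows["phase"] = [calendar.phase_of(d) for d in windows["date"]]
print("\nmean moving-window DFC per phase (2 simulated animals):")
print(windows.groupby("phase")["dfc"].mean().round(3).to_string())
print("\nThe injected festival arrhythmia (profile flattened toward constant "
      "rate) pulls the DFC down from its baseline — the package's stress "
      "indicator.")
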