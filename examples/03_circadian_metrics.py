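"""Daily circadian metrics: diurnality index, activity onset vs civil dusk.

The per-minute activity proxy (aSD, summed per-axis burst SD) is cut into
dawn-to-dawn days; DI contrasts day/night activity rates, and TSdusk gives
the signed minutes between nightly activity onset and civil dusk.
"""

from hoglog import EffectConfig, StudyConfig, generate_minutes, rhythm_table, seasonal_twilight
from hoglog.synthetic import _twilight_dates

config = StudyConfig(
    n_individuals=2, pre_days=4, festival_days=4, post_days=0, seed=11,
    effects=EffectConfig(onset_delay_min=45.0),
)
minutes, onsets, _ = generate_minutes(config)
features = minutes.rename(columns={"asd_true": "asd"})[
    ["individual_id", "timestamp", "asd"]
].copy()
features["odba"] = features["asd"] * 0.5  # stand-in; real ODBA comes from featurize

table = rhythm_table(features, seasonal_twilight(_twilight_dates(config)), min_bursts=1430)
calendar = config.calendar()
table["phase"] = [calendar.phase_of(d) for d in table["date"]]

print(table[["individual_id", "date", "phase", "DI", "TSdusk_min"]].round(3).to_string(index=False))
means = table.groupby("phase")[["DI", "TSdusk_min"]].mean().round(2)
print("\nphase means:")
print(means)
print("\nDI stays strongly negative (nocturnal animal); TSdusk shifts from "
      "about 0 (onset at dusk) to about +45 min during the disturbance — "
      "the injected onset delay.")
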