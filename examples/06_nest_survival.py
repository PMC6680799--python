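"""Nest-utilization survival: spells, Kaplan-Meier curve, log-rank test.

Daily nest checks become maximal same-nest spells (censored at phase
boundaries and monitoring end); the survival function of spell duration is
compared between festival and pooled non-festival days, per sex.
"""

import numpy as np

from hoglog import EffectConfig, StudyConfig, build_spells, km_curve, nest_survival_summary
from hoglog.synthetic import _generate_nests, _individual_table

config = StudyConfig(
    n_individuals=8, pre_days=10, festival_days=10, post_days=3, seed=9,
    effects=EffectConfig(male_nest_hazard_mult=3.0),
)
rng = np.random.default_rng(7)
individuals = _individual_table(config, rng)
checks, _ = _generate_nests(config, rng, individuals)

spells = build_spells(checks, config.calendar())
print(f"{len(spells)} spells from {len(checks)} daily checks")

males_fest = spells[(spells["sex"] == "m") & (spells["phase_group"] == "festival")]
km = km_curve(males_fest["duration_days"], males_fest["event"])
print("\nKaplan-Meier survival of male festival nest spells:")
print(km.round(3).to_string(index=False))

summary = nest_survival_summary(spells)
print("\nper-sex log-rank comparison (festival vs non-festival):")
print(summary[["sex", "z", "p", "n_spells", "n_nest_days"]].round(4).to_string(index=False))
print("\nA positive Z means more nest changes than expected during the "
      "festival; with the injected 3x male hazard only the males reach "
      "significance.")
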