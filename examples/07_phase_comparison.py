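"""Per-individual change estimation with the pairwise-difference mixed model.

Every festival day's value is differenced against every baseline day's value
(festival minus pre); a random-intercept model (REML) shrinks each animal's
mean difference toward the population mean, and an animal counts as changed
when its 95% interval excludes zero.
"""

import numpy as np
import pandas as pd

from hoglog import PhaseCalendar, estimate_changes, summarize_changes

calendar = PhaseCalendar()
rng = np.random.default_rng(2)

# four animals: two clear decreases, one increase, one unchanged
true_effects = {"id01": -2.0, "id02": -1.5, "id03": +2.0, "id04": 0.0}
rows = []
for ind, eff in true_effects.items():
    for d in calendar.pre_dates:
        rows.append((ind, d, 10.0 + rng.normal(0, 0.8)))
    for d in calendar.festival_dates:
        rows.append((ind, d, 10.0 + eff + rng.normal(0, 0.8)))
daily = pd.DataFrame(rows, columns=["individual_id", "date", "value"])

est = estimate_changes(daily, calendar)
print("per-individual predicted change (festival - pre), 95% interval:")
print(est.table.round(3).to_string(index=False))
print(f"\npopulation mean change mu = {est.mu:.3f} "
      f"(sigma_b = {np.sqrt(est.sigma2_b):.3f}, sigma_e = {np.sqrt(est.sigma2_e):.3f})")
print("\nsummary:")
print(summarize_changes({"demo_parameter": est}).to_string(index=False))
print("\nThe model recovers each animal's injected effect and its sign; the "
      "unchanged animal's interval straddles zero.  Intervals use the "
      "design-corrected effective replication, since the 361 pairwise "
      "differences per animal reuse only 19 + 19 daily values.")
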