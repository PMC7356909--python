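"""Group discrimination: mixed ANOVA effects and ROC sensitivity/specificity.

Two groups of subjects differ in flush amplitude; the mixed
between(group)-within(time) ANOVA quantifies the group effect with
partial eta squared, and the ROC curve summarises how well the delta-Cr
score separates the groups at a single (concentration, time) cell.
"""

import numpy as np
import pandas as pd

from niaflush import apply_bonferroni, group_time_effects, roc_analysis

rng = np.random.default_rng(7)
times = (3, 5, 10, 15)
time_shape = {3: 0.6, 5: 0.8, 10: 1.0, 15: 1.0}

rows = []
for group, amplitude, n in (("HC", 12.0, 20), ("SZ", 5.0, 20)):
    for i in range(n):
        subject_amp = amplitude * rng.uniform(0.6, 1.2)
        for t in times:
            rows.append({
                "subject": f"{group}{i}", "group": group, "time": t,
                "value": subject_amp * time_shape[t] + rng.normal(0, 2),
            })
table = pd.DataFrame(rows)

effects = group_time_effects(table, variable="delta_Cr_mean")
apply_bonferroni(effects, alpha=0.05, m=27)
print(f"{'factor':>14} {'F':>8} {'p':>10} {'eta_p^2':>8}  significant")
for e in effects:
    print(f"{e.factor:>14} {e.F:8.2f} {e.p:10.2e} {e.partial_eta_sq:8.3f}  "
          f"{e.significant}")

scores = table[table["time"] == 10].set_index("subject")["value"]
labels = table[table["time"] == 10].set_index("subject")["group"] == "HC"
roc = roc_analysis(scores.to_numpy(), labels.to_numpy())
print(f"\nROC at the 10-min cell: AUC={roc.auc:.3f}, operating point "
      f"sensitivity={roc.operating_sensitivity:.2f}, "
      f"specificity={roc.operating_specificity:.2f}")
print("\nThe group effect survives a Bonferroni family of 27 tests; the AUC "
      "reflects the overlap of the two groups' flush-amplitude distributions.")
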