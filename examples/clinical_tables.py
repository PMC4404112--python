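"""Univariate clinical-table statistics and matched-pair construction.

Recomputes discharge-disposition percentages from a published-style count
table, tests them with Fisher's exact test, and demonstrates greedy
matched-pair construction under hard criteria (gender, 28-day survival,
sampled timepoints) with minimal summed AIS distance.
"""

import numpy as np

from traumadfr import ClinicalCountTable, SampleMeta, contingency_stats, match_pairs

# discharge disposition of 1,395 young vs 533 aged trauma patients
table = ClinicalCountTable(
    ("Home", "Inpatient rehabilitation", "LTAC", "Skilled nursing facility",
     "Other", "Death (as inpatient)"),
    ("young", "aged"),
    np.array([[480, 66], [357, 96], [52, 38], [283, 193], [43, 12], [180, 128]]),
    (1395, 533))

print("disposition          young%   aged%   Fisher p")
for row in table.row_labels:
    r = contingency_stats(table, row)
    print(f"{row:<22s}{r.percents[0]:5.1f}  {r.percents[1]:6.1f}   {r.fisher_p:.2g}")
print("\nAged survivors are far likelier to be discharged to skilled nursing "
      "(36.2% vs 20.3%) than home (12.4% vs 34.4%).")


def patient(pid, group, gender, ais, survived=True):
    return [SampleMeta(f"{pid}_d{t:g}", pid, group, "complicated", t, gender,
                       ais, survived) for t in (0.5, 1.0, 4.0)]


meta = (patient("A01", "aged", "male", (3, 4, 0)) +
        patient("A02", "aged", "female", (2, 2, 1)) +
        patient("Y01", "young", "male", (3, 5, 0)) +
        patient("Y02", "young", "female", (2, 3, 1)) +
        patient("Y03", "young", "male", (1, 0, 0), survived=False))
pairs = match_pairs(meta)
print("\nmatched pairs (aged, young) with summed |ΔAIS|:")
for (a, y), c in zip(pairs.pairs, pairs.costs):
    print(f"  {a} - {y}  (cost {c:g})")
print(f"unmatched young: {pairs.unmatched_young}")
print("\nY03 stays unmatched: no aged non-survivor shares its profile — "
      "survival and gender are hard criteria, AIS distance only ranks "
      "admissible candidates.")
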