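"""Descriptive summary of the packaged 27-patient TLE cohort table.

Loads the cohort fixture (demographics, outcome after 3 months of
levetiracetam, maintenance dose) and prints the descriptives a clinical
report would state: counts with percentages, means with sample SDs.
"""

from microstates import load_cohort, summarize_cohort

cohort = load_cohort()
s = summarize_cohort(cohort)

print(f"n = {s['n']} patients, {s['sex']['F']['count']} female")
print(f"age: {s['age']['mean']} +/- {s['age']['sd']} years "
      f"(range {s['age']['min']:.0f}-{s['age']['max']:.0f})")
print(f"LEV dose: {s['lev_dose_mg']['mean']} +/- {s['lev_dose_mg']['sd']} mg")
for code, row in s["outcome"].items():
    print(f"outcome {code}: {row['count']} ({row['pct']}%)")
print(f"structural aetiology: {s['structural_aetiology']['count']} "
      f"({s['structural_aetiology']['pct']}%)")
print(f"adverse events: {s['adverse_events']['count']} "
      f"({s['adverse_events']['pct']}%)")
# Percentages are 100*count/27 rounded half-up to one decimal; SDs use n-1.
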