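"""Generate a small synthetic cohort and look at its structure.

Builds 20 patients with repeated examinations, prints the severity-label
histogram (note the imbalance: severe dyskinesia is nearly absent) and
writes the cohort to disk as CSV recordings + JSON manifest.
"""

from collections import Counter
from pathlib import Path

from pdsense import SyntheticConfig, generate_cohort, save_cohort

config = SyntheticConfig(n_patients=20, seed=42)
cohort = generate_cohort(config)

print(f"patients: {len(cohort.patients)}, examinations: {len(cohort.examinations)}")
for symptom in ("tremor", "bradykinesia", "stiffness", "dyskinesia"):
    counts = Counter(e.labels.symptom(symptom) for e in cohort.examinations)
    histogram = " ".join(f"{k}:{counts.get(k, 0)}" for k in range(5))
    print(f"{symptom:13s} {histogram}")
trs = [e.labels.trs_clinician for e in cohort.examinations]
print(f"clinician TRS range: {min(trs)} .. {max(trs)} (negative = parkinsonian)")

out = Path("scratch/example_cohort")
save_cohort(cohort, out)
print(f"wrote cohort to {out}/ (config.yaml, manifest.json, per-recording CSVs)")
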