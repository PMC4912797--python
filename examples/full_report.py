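"""Run the complete analysis pipeline on a cohort CSV and list its outputs.

Writes a synthetic cohort to disk, then produces the full structured report:
descriptive table, logistic odds-ratio tables, five AUCs, the paired
equality tests, cut-points, and LOWESS exports.
"""

import dataclasses
import json
import tempfile
from pathlib import Path

import vdscore as v
from vdscore.synthetic_cohort import default_alpha

workdir = Path(tempfile.mkdtemp(prefix="vdscore_example_"))
config = dataclasses.replace(v.GeneratorConfig.default("dcci_model"), n=310, seed=7)
cohort = v.generate_cohort(config, alpha=default_alpha(config))
csv_path = workdir / "cohort.csv"
v.write_cohort(cohort, csv_path)

out_dir = workdir / "report"
v.run_analysis(v.AnalysisConfig(cohort_path=str(csv_path), out_dir=str(out_dir)))

print(f"outputs in {out_dir}:")
for path in sorted(out_dir.iterdir()):
    print(f"  {path.name}")

payload = json.loads((out_dir / "report.json").read_text())
print("\nAUCs:")
for name, entry in payload["aucs"].items():
    print(f"  {name:<22} {entry['auc']:.3f} "
          f"({entry['ci_low']:.3f}-{entry['ci_high']:.3f})")
print("\ncomparisons (chi2, p):")
for name, entry in payload["comparisons"].items():
    print(f"  {name:<34} {entry['chi2']:6.2f}  {entry['p']:.3f}")

# Interpretation: the report bundles every published-style quantity for one
# cohort; the same files are produced by `vdscore analyze` on the shell.
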