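"""Smooth DCCI against 25OHD and compare slopes in two biomarker windows.

A LOWESS curve (tricube weights, bisquare robustness) summarizes how
comorbidity burden varies with vitamin D status; the deficient range
(< 10 ng/mL) is expected to be markedly steeper than the range above it.
"""

import dataclasses

import vdscore as v
from vdscore.synthetic_cohort import default_alpha

config = dataclasses.replace(v.GeneratorConfig.default("dcci_model"), n=3000, seed=11)
cohort = v.generate_cohort(config, alpha=default_alpha(config))

fit = v.lowess_fit(cohort.column("vitd_25ohd"),
                   cohort.column("dcci").astype(float))

slope_deficient = v.window_slope(fit, 0.0, 10.0)
slope_moderate = v.window_slope(fit, 10.0, 30.0)
print(f"average slope on (0, 10) ng/mL:  {slope_deficient:+.3f} DCCI points per ng/mL")
print(f"average slope on (10, 30) ng/mL: {slope_moderate:+.3f} DCCI points per ng/mL")

# Interpretation: the curve falls much faster below 10 ng/mL — comorbidity
# burden concentrates in the severely deficient, then the relationship
# flattens out.
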