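"""Simulate the default 200-case cohort of acetowhite response functions.

Each case is one intensity trace: 10 pre-acetic-acid baseline frames around a
basal level of 100 gray levels, then 180 post-application frames following
class-specific whitening kinetics plus lighting noise and drift.
"""

import numpy as np

import acetowhite as aw
from acetowhite.synthetic import class_mean_traces

series = aw.generate_series(aw.GeneratorConfig(seed=7))
labels = [s.label for s in series]
print(f"cases: {len(series)}, trace length: {series[0].values.size}")
for cls in aw.TissueClass:
    n = labels.count(cls.value)
    print(f"  {cls.value:<12} n={n:<3} binary={cls.binary_label}")

means = class_mean_traces(series)
print("\npeak mean percent change vs basal (whitening strength):")
for cls, trace in means.items():
    peak = 100.0 * (trace[10:].max() - 100.0) / 100.0
    print(f"  {cls:<12} {peak:6.1f}%")
print(
    "\nHSIL whitens most; inflammation and ectopy whiten nearly as much as "
    "LSIL, which is exactly the benign/lesion confound that limits "
    "colposcopy's specificity."
)
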