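"""Build the five representations of one acetowhite response function.

Shows standardization (percent change vs basal), the fitted whitening
polynomial, and the PLA / PSA symbol strings under a calibrated scheme.
"""

import numpy as np

import acetowhite as aw
from acetowhite.representations import standardize_dataset

series = aw.generate_series(aw.GeneratorConfig(seed=7))
raw = aw.series_to_dataset(series)
std = standardize_dataset(raw, 10)
scheme = aw.calibrate_scheme(std.features, aw.uniform_boundaries(180, 12), alphabet_size=5)
reps = aw.build_representations(raw, 10, scheme)

case = 199  # an HSIL case (classes are emitted in canonical order)
print(f"case label: {raw.labels[case]}")
print(f"standardized (first 5 of 180): {np.round(reps['standardized'].features[case][:5], 2)}")
print(f"fitted polynomial coefficients: {np.round(reps['parameters'].features[case], 2)}")
print(f"PLA symbols ({scheme.n_segments} segments, alphabet {scheme.alphabet_size}): "
      f"{reps['pla'].features[case].astype(int)}")
print(f"PSA symbols (slope alphabet -3..3): {reps['psa'].features[case].astype(int)}")
print(
    "\nThe 180-point trace compresses to 12 PLA symbols; high symbols mark "
    "segments of strong whitening, and positive/negative PSA symbols mark "
    "the whitening rise and fade."
)
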