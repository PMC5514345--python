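"""Cross-validate the three classifiers on every representation.

Reproduces the shape of the study's comparison grid on the synthetic cohort:
3 methods x 5 representations, 10-fold stratified CV, binary labels.
"""

import acetowhite as aw
from acetowhite.classifiers import make_classifier
from acetowhite.representations import standardize_dataset

series = aw.generate_series(aw.GeneratorConfig(seed=7))
raw = aw.series_to_dataset(series)
std = standardize_dataset(raw, 10)
scheme = aw.calibrate_scheme(std.features, aw.uniform_boundaries(180, 12), 5)
reps = aw.build_representations(raw, 10, scheme)

print(f"{'method':<6} {'representation':<14} {'acc':>5} {'sens':>5} {'spec':>5} {'MCC':>6}")
for method in ("knn", "nb", "c45"):
    for tag in ("standardized", "adjusted", "parameters", "pla", "psa"):
        cv = aw.cross_validate(
            reps[tag].binarized(),
            lambda: make_classifier(method),
            k=10,
            seed=7,
            class_list=["positive", "negative"],
        )
        row = cv.report.per_class["positive"]
        print(
            f"{method:<6} {tag:<14} {cv.confusion.accuracy:5.2f} "
            f"{row['tp_rate']:5.2f} {row['specificity']:5.2f} {row['mcc']:6.3f}"
        )
print(
    "\nSynthetic accuracies exceed the clinical ones because the generator "
    "has no between-patient kinetic variability; the grid still shows the "
    "discrete PLA encoding retaining the signal at a fraction of the "
    "dimensionality."
)
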