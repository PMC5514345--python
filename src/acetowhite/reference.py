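"""Published reference confusion matrices for the acetowhitening study.

The original 200-patient colposcopy recordings are not deposited anywhere,
but the study's best classifier (1-nearest-neighbor on the discrete PLA
representation) is reported as printed confusion matrices — one binary
(positive/negative for a precancerous lesion) and one six-class.  They are
packaged here as small CSV fixtures so the full metric suite can be
regression-tested against reported results without any image data.
"""

from __future__ import annotations

from importlib import resources

from .evaluation import ConfusionMatrix


def _load(name: str) -> ConfusionMatrix:
    with resources.as_file(resources.files("acetowhite") / "data" / name) as path:
        return ConfusionMatrix.from_csv(path)


def binary_knn_pla_confusion() -> ConfusionMatrix:
    """2x2 reference matrix (positive first): TP=56, FN=37, FP=23, TN=84."""
    return _load("knn_pla_binary_confusion.csv")


def multiclass_knn_pla_confusion() -> ConfusionMatrix:
    """6x6 reference matrix over atrophy/inflammation/ectopy/normal/LSIL/HSIL."""
    return _load("knn_pla_multiclass_confusion.csv")
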