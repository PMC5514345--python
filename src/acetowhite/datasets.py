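"""Core containers: tissue classes, acetowhite response series, labeled datasets.

The unit of analysis is the acetowhite response function (Awrf): the mean
grayscale intensity of a cervical tissue region traced across a colposcopic
image sequence (a short pre-acetic-acid baseline followed by a 3-minute
post-application recording at 1 frame/s).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TissueClass(str, enum.Enum):
    """Six cervical tissue types, in the study's canonical order."""

    ATROPHY = "atrophy"
    INFLAMMATION = "inflammation"
    ECTOPY = "ectopy"
    NORMAL = "normal"
    LSIL = "LSIL"
    HSIL = "HSIL"

    @property
    def binary_label(self) -> str:
        """Binary diagnosis: squamous intraepithelial lesions are positive."""
        return "positive" if self in (TissueClass.LSIL, TissueClass.HSIL) else "negative"


#: Canonical multiclass label order (atrophy ... HSIL).
MULTICLASS_ORDER: tuple[str, ...] = tuple(c.value for c in TissueClass)

#: Binary label order: positive class first (row 1 of a 2x2 confusion matrix).
BINARY_ORDER: tuple[str, str] = ("positive", "negative")


def to_binary(label: str | TissueClass) -> str:
    """Map a six-class tissue label onto the positive/negative dichotomy."""
    if isinstance(label, TissueClass):
        return label.binary_label
    return TissueClass(label).binary_label


@dataclass
class AwrfSeries:
    """One region's intensity trace over the full image sequence.

    Parameters
    ----------
    values : array of length n_baseline + n_post
        Mean region intensity per frame (grayscale units).
    n_baseline : int
        Number of pre-acetic-acid reference frames at the start.
    case_id : str
        Identifier of the patient/case.
    label : str or None
        Tissue class if known.
    """

    values: np.ndarray
    n_baseline: int
    case_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("series values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")
        if not 0 < self.n_baseline < self.values.size:
            raise ValueError("n_baseline must leave at least one post-acid frame")

    @property
    def n_post(self) -> int:
        return self.values.size - self.n_baseline

    @property
    def baseline(self) -> np.ndarray:
        return self.values[: self.n_baseline]

    @property
    def post(self) -> np.ndarray:
        return self.values[self.n_baseline :]


@dataclass
class LabeledDataset:
    """A feature matrix with one class label per case.

    ``features`` are continuous for the standardized / polynomial-adjusted /
    parameter representations and small integers for the PLA / PSA symbol
    representations (``discrete=True``).
    """

    features: np.ndarray
    labels: np.ndarray
    representation_tag: str = ""
    discrete: bool = False
    case_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix (cases x features)")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per case required")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("missing/non-finite feature values are not supported")
        if not self.case_ids:
            self.case_ids = [f"case{i:04d}" for i in range(len(self.labels))]

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def binarized(self) -> "LabeledDataset":
        """Collapse six-class labels to positive/negative."""
        labels = np.array([to_binary(l) for l in self.labels], dtype=object)
        return LabeledDataset(
            self.features, labels, self.representation_tag, self.discrete, list(self.case_ids)
        )

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            self.features[idx],
            self.labels[idx],
            self.representation_tag,
            self.discrete,
            [self.case_ids[i] for i in idx],
        )


def series_to_dataset(series: list[AwrfSeries], tag: str = "raw") -> LabeledDataset:
    """Stack equal-length series into a LabeledDataset of raw traces."""
    if not series:
        raise ValueError("empty series list")
    lengths = {s.values.size for s in series}
    if len(lengths) != 1:
        raise ValueError("all series must have equal length")
    return LabeledDataset(
        features=np.vstack([s.values for s in series]),
        labels=np.array([s.label for s in series], dtype=object),
        representation_tag=tag,
        case_ids=[s.case_id for s in series],
    )


def series_to_frame(series: list[AwrfSeries]) -> pd.DataFrame:
    """Tabulate series as rows: case_id, class, t0..t{T-1}."""
    length = series[0].values.size
    cols = [f"t{i}" for i in range(length)]
    df = pd.DataFrame([s.values for s in series], columns=cols)
    df.insert(0, "class", [s.label for s in series])
    df.insert(0, "case_id", [s.case_id for s in series])
    return df


def frame_to_series(df: pd.DataFrame, n_baseline: int) -> list[AwrfSeries]:
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    tcols.sort(key=lambda c: int(c[1:]))
    return [
        AwrfSeries(
            values=row[tcols].to_numpy(dtype=float),
            n_baseline=n_baseline,
            case_id=str(row["case_id"]),
            label=None if pd.isna(row["class"]) else str(row["class"]),
        )
        for _, row in df.iterrows()
    ]


def write_series_csv(series: list[AwrfSeries], path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_series_csv(path, n_baseline: int = 10) -> list[AwrfSeries]:
    return frame_to_series(pd.read_csv(path), n_baseline=n_baseline)
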