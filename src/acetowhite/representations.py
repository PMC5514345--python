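"""Time-series representations of acetowhite response functions.

Five representations are produced from a raw trace:

1. **standardized** — percent change of the post-acid signal relative to the
   basal (pre-acid) intensity;
2. **adjusted** — the standardized series replaced by its least-squares fit to
   the whitening-kinetics polynomial (noise-reduced curve);
3. **parameters** — the five fitted polynomial coefficients themselves;
4. **PLA** — piecewise linear approximation: per-segment mean mapped to an
   alphabet interval symbol;
5. **PSA** — piecewise slope approximation: per-segment slope mapped to one of
   seven symbols (three negative, zero, three positive).

The whitening-kinetics model is a five-parameter polynomial on time scaled to
[0, 1] over the post-acid segment,

    f(t) = th0 + th1*sqrt(t) + th2*t + th3*t^2 + th4*t^3 ,

whose sqrt(t) term captures the fast initial whitening onset followed by the
slower polynomial decay.  PLA and PSA use a *discretization scheme*: variable
segment boundaries along time (word sizes) plus value cut points along the
y-axis (alphabet size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datasets import AwrfSeries, LabeledDataset


# ---------------------------------------------------------------------------
# standardization and polynomial model
# ---------------------------------------------------------------------------


@dataclass
class StandardizedSeries:
    """Percent-change values over the post-acid segment, plus the basal level."""

    values: np.ndarray
    basal: float
    case_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class PolynomialParams:
    theta: np.ndarray  # (th0..th4)
    fit_rss: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (5,):
            raise ValueError("theta must have five coefficients")


def time_grid(n_post: int) -> np.ndarray:
    """Scaled time grid over the post-acid segment: n_post points on [0, 1]."""
    if n_post < 2:
        raise ValueError("need at least two post-acid frames")
    return np.linspace(0.0, 1.0, n_post)


def design_matrix(t: np.ndarray) -> np.ndarray:
    """Basis columns {1, sqrt(t), t, t^2, t^3} of the kinetics polynomial."""
    t = np.asarray(t, dtype=float)
    return np.column_stack([np.ones_like(t), np.sqrt(t), t, t**2, t**3])


def evaluate_polynomial(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    return design_matrix(t) @ np.asarray(theta, dtype=float)


def standardize(series: AwrfSeries) -> StandardizedSeries:
    """Percent change of the post-acid signal relative to the basal value.

    The basal value is the mean of the pre-acid reference frames; each
    post-acid value x becomes 100 * (x - basal) / basal.
    """
    basal = float(series.baseline.mean())
    if basal <= 0:
        raise ValueError(f"basal intensity must be positive, got {basal}")
    values = 100.0 * (series.post - basal) / basal
    return StandardizedSeries(values=values, basal=basal, case_id=series.case_id, label=series.label)


def fit_polynomial(series: StandardizedSeries | np.ndarray) -> PolynomialParams:
    """Ordinary least squares fit of the five-parameter whitening polynomial."""
    values = series.values if isinstance(series, StandardizedSeries) else np.asarray(series, float)
    if values.size < 5:
        raise ValueError("need at least five points to fit five coefficients")
    X = design_matrix(time_grid(values.size))
    theta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ theta
    return PolynomialParams(theta=theta, fit_rss=float(resid @ resid))


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


@dataclass
class DiscretizationScheme:
    """Variable-word-size segmentation plus alphabet cut points.

    ``boundaries`` are strictly increasing segment *end* indices; the last one
    equals the series length, so segment i covers
    [boundaries[i-1], boundaries[i]).  ``cuts`` are strictly increasing value
    thresholds; with m cuts the alphabet has m+1 interval symbols.
    ``slope_cuts`` (six thresholds, symmetric about zero) drive the PSA
    seven-symbol slope mapping.
    """

    boundaries: list[int]
    cuts: list[float] = field(default_factory=list)
    slope_cuts: list[float] | None = None

    def __post_init__(self) -> None:
        self.boundaries = [int(b) for b in self.boundaries]
        self.cuts = [float(c) for c in self.cuts]
        if not self.boundaries or self.boundaries[0] <= 0:
            raise ValueError("boundaries must be positive end indices")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing (no empty segments)")
        if any(c2 <= c1 for c1, c2 in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cuts must be strictly increasing")
        if self.slope_cuts is not None:
            validate_slope_cuts(self.slope_cuts)

    @property
    def n_segments(self) -> int:
        return len(self.boundaries)

    @property
    def alphabet_size(self) -> int:
        return len(self.cuts) + 1

    def segments(self) -> list[tuple[int, int]]:
        starts = [0] + self.boundaries[:-1]
        return list(zip(starts, self.boundaries))

    def check_tiles(self, n: int) -> None:
        if self.boundaries[-1] != n:
            raise ValueError(
                f"scheme boundaries end at {self.boundaries[-1]} but series has {n} points"
            )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"boundaries": self.boundaries, "cuts": self.cuts, "slope_cuts": self.slope_cuts},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationScheme":
        d = json.loads(text)
        return cls(
            boundaries=d["boundaries"], cuts=d.get("cuts", []), slope_cuts=d.get("slope_cuts")
        )


@dataclass
class DiscreteSeries:
    symbols: np.ndarray
    mode: str  # "PLA" or "PSA"

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)


def validate_slope_cuts(slope_cuts) -> np.ndarray:
    sc = np.asarray(slope_cuts, dtype=float)
    if sc.shape != (6,):
        raise ValueError("PSA needs exactly six slope thresholds")
    if np.any(np.diff(sc) <= 0):
        raise ValueError("slope thresholds must be strictly increasing")
    if not np.allclose(sc, -sc[::-1]):
        raise ValueError("slope thresholds must be symmetric about zero")
    return sc


def segment_means(values: np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    scheme.check_tiles(values.size)
    return np.array([values[a:b].mean() for a, b in scheme.segments()])


def segment_slopes(values: np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    """Least-squares line slope within each segment, on the scaled time grid."""
    values = np.asarray(values, dtype=float)
    scheme.check_tiles(values.size)
    t = time_grid(values.size)
    slopes = []
    for a, b in scheme.segments():
        if b - a == 1:
            slopes.append(0.0)  # a single point carries no slope information
            continue
        ts, ys = t[a:b], values[a:b]
        tc = ts - ts.mean()
        slopes.append(float(tc @ (ys - ys.mean()) / (tc @ tc)))
    return np.array(slopes)


def discretize_pla(
    series: StandardizedSeries | np.ndarray, scheme: DiscretizationScheme
) -> DiscreteSeries:
    """Map each segment's mean to the alphabet interval containing it.

    Intervals are half-open [cut_i, cut_{i+1}); the lowest is unbounded below
    and the highest unbounded above, so every mean receives a symbol in
    [0, alphabet_size).
    """
    values = series.values if isinstance(series, StandardizedSeries) else np.asarray(series, float)
    if not scheme.cuts:
        raise ValueError("scheme has no alphabet cuts")
    means = segment_means(values, scheme)
    symbols = np.searchsorted(np.asarray(scheme.cuts), means, side="right")
    return DiscreteSeries(symbols=symbols, mode="PLA")


def discretize_psa(
    series: StandardizedSeries | np.ndarray,
    scheme: DiscretizationScheme,
    slope_cuts=None,
) -> DiscreteSeries:
    """Map each segment's slope to one of the seven symbols {-3..3}.

    The six thresholds split the slope axis into seven intervals; the central
    interval (around zero slope) maps to symbol 0.
    """
    values = series.values if isinstance(series, StandardizedSeries) else np.asarray(series, float)
    sc = validate_slope_cuts(slope_cuts if slope_cuts is not None else scheme.slope_cuts)
    slopes = segment_slopes(values, scheme)
    symbols = np.searchsorted(sc, slopes, side="right") - 3
    return DiscreteSeries(symbols=symbols, mode="PSA")


# ---------------------------------------------------------------------------
# scheme calibration and dataset-level assembly
# ---------------------------------------------------------------------------


def uniform_boundaries(n_post: int, n_segments: int) -> list[int]:
    """Equal-size segmentation (last segment absorbs the remainder)."""
    if not 1 <= n_segments <= n_post:
        raise ValueError("n_segments must be in [1, n_post]")
    edges = np.linspace(0, n_post, n_segments + 1).round().astype(int)
    return list(np.unique(edges[1:]))


def pla_cuts_from_training(values_matrix: np.ndarray, boundaries, alphabet_size: int) -> list[float]:
    """Equal-frequency alphabet cuts from pooled training segment means."""
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be at least 2")
    scheme = DiscretizationScheme(boundaries=list(boundaries))
    pooled = np.concatenate([segment_means(row, scheme) for row in np.atleast_2d(values_matrix)])
    qs = np.linspace(0, 1, alphabet_size + 1)[1:-1]
    cuts = np.quantile(pooled, qs)
    cuts = np.unique(cuts)
    if cuts.size == 0:  # constant training data: fall back to a single cut
        cuts = np.array([pooled[0]])
    return [float(c) for c in cuts]


def psa_cuts_from_training(values_matrix: np.ndarray, boundaries) -> list[float]:
    """Symmetric slope thresholds from quantiles of absolute training slopes."""
    scheme = DiscretizationScheme(boundaries=list(boundaries))
    pooled = np.abs(
        np.concatenate([segment_slopes(row, scheme) for row in np.atleast_2d(values_matrix)])
    )
    pos = np.quantile(pooled, [0.25, 0.5, 0.75])
    # enforce strict increase for degenerate (near-constant) training data
    eps = max(1e-9, 1e-6 * (pos[-1] if pos[-1] > 0 else 1.0))
    pos = np.maximum.accumulate(pos + eps * np.arange(1, 4))
    return [float(x) for x in np.concatenate([-pos[::-1], pos])]


def calibrate_scheme(
    values_matrix: np.ndarray, boundaries, alphabet_size: int
) -> DiscretizationScheme:
    """Fill a segmentation with training-derived PLA cuts and PSA slope cuts."""
    return DiscretizationScheme(
        boundaries=list(boundaries),
        cuts=pla_cuts_from_training(values_matrix, boundaries, alphabet_size),
        slope_cuts=psa_cuts_from_training(values_matrix, boundaries),
    )


def standardize_dataset(raw: LabeledDataset, n_baseline: int) -> LabeledDataset:
    """Standardize every raw trace in a dataset (rows are full-length series)."""
    out = []
    for row in raw.features:
        s = AwrfSeries(values=row, n_baseline=n_baseline)
        out.append(standardize(s).values)
    return LabeledDataset(
        np.vstack(out), raw.labels, "standardized", discrete=False, case_ids=list(raw.case_ids)
    )


def build_representations(
    raw: LabeledDataset, n_baseline: int, scheme: DiscretizationScheme
) -> dict[str, LabeledDataset]:
    """All five representations of a raw-series dataset, keyed by tag."""
    std = standardize_dataset(raw, n_baseline)
    t = time_grid(std.n_features)
    params, adjusted = [], []
    for row in std.features:
        p = fit_polynomial(row)
        params.append(p.theta)
        adjusted.append(evaluate_polynomial(p.theta, t))
    pla = np.vstack([discretize_pla(row, scheme).symbols for row in std.features])
    psa = np.vstack([discretize_psa(row, scheme).symbols for row in std.features])
    ids = list(raw.case_ids)
    return {
        "standardized": std,
        "adjusted": LabeledDataset(np.vstack(adjusted), raw.labels, "adjusted", case_ids=ids),
        "parameters": LabeledDataset(np.vstack(params), raw.labels, "parameters", case_ids=ids),
        "pla": LabeledDataset(pla, raw.labels, "pla", discrete=True, case_ids=ids),
        "psa": LabeledDataset(psa, raw.labels, "psa", discrete=True, case_ids=ids),
    }
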