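"""Synthetic colposcopic data with known ground truth.

Real acetowhitening recordings are not publicly deposited, so every pipeline
stage is exercised on simulated data that reproduces the statistical structure
the analysis assumes: class-dependent whitening kinetics shaped like the
five-parameter polynomial, additive lighting noise and slow illumination
drift, inter-frame translational jitter from patient motion, and the study's
six-class composition (15 atrophy / 24 inflammation / 20 ectopy / 48 normal /
37 LSIL / 56 HSIL = 200 cases, 93 positive).

The default kinetics profile orders peak percent whitening as
HSIL > LSIL >~ ectopy >~ inflammation > atrophy > normal.  Crucially, the
benign reactive classes (inflammation, ectopy) whiten almost as strongly as
LSIL — the confusability between benign acetowhite reactions and true
squamous intraepithelial lesions that limits colposcopy's specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import AwrfSeries, TissueClass
from .imaging import ImageSequence, RegionSpec
from .representations import evaluate_polynomial, time_grid


@dataclass
class ClassKinetics:
    """Whitening kinetics of one tissue class.

    theta: coefficients of the percent-change polynomial on scaled time;
    noise_sd: SD of per-frame additive lighting noise (intensity units);
    drift_amplitude: amplitude of the slow sinusoidal illumination drift.
    """

    theta: np.ndarray
    noise_sd: float = 2.0
    drift_amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (5,):
            raise ValueError("theta must have five coefficients")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be nonnegative")


#: Peak percent change roughly 32 / 19 / 15 / 13 / 4 / 1 for
#: HSIL / LSIL / ectopy / inflammation / atrophy / normal.
DEFAULT_KINETICS: dict[TissueClass, ClassKinetics] = {
    TissueClass.HSIL: ClassKinetics(theta=[0.0, 55.0, -5.0, -25.0, 5.0]),
    TissueClass.LSIL: ClassKinetics(theta=[0.0, 35.0, -5.0, -15.0, 3.0]),
    TissueClass.ECTOPY: ClassKinetics(theta=[0.0, 30.0, -6.0, -14.0, 3.0]),
    TissueClass.INFLAMMATION: ClassKinetics(theta=[0.0, 26.0, -6.0, -13.0, 3.0]),
    TissueClass.ATROPHY: ClassKinetics(theta=[0.0, 10.0, -3.0, -5.0, 1.0]),
    TissueClass.NORMAL: ClassKinetics(theta=[0.0, 3.0, -1.0, -1.5, 0.3]),
}

#: Study composition: 200 cases, 107 negative / 93 positive.
DEFAULT_CLASS_COUNTS: dict[TissueClass, int] = {
    TissueClass.ATROPHY: 15,
    TissueClass.INFLAMMATION: 24,
    TissueClass.ECTOPY: 20,
    TissueClass.NORMAL: 48,
    TissueClass.LSIL: 37,
    TissueClass.HSIL: 56,
}


@dataclass
class GeneratorConfig:
    class_counts: dict[TissueClass, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    n_baseline: int = 10
    n_post: int = 180
    frame_shape: tuple[int, int] = (240, 352)
    jitter_sd: float = 1.0
    basal: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {}
        for cls, n in self.class_counts.items():
            cls = TissueClass(cls)
            if n < 0:
                raise ValueError(f"negative case count for {cls.value}")
            counts[cls] = int(n)
        self.class_counts = counts
        if self.basal <= 0:
            raise ValueError("basal intensity must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")

    @property
    def n_cases(self) -> int:
        return sum(self.class_counts.values())


#: One cycle of illumination drift over the post-acid recording (3 minutes).
DRIFT_CYCLES = 1.0


def _one_series(
    config: GeneratorConfig, kin: ClassKinetics, rng: np.random.Generator
) -> np.ndarray:
    t = time_grid(config.n_post)
    clean_post = config.basal * (1.0 + evaluate_polynomial(kin.theta, t) / 100.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = kin.drift_amplitude * np.sin(2.0 * np.pi * DRIFT_CYCLES * t + phase)
    noise = rng.normal(0.0, kin.noise_sd, size=config.n_baseline + config.n_post)
    values = np.empty(config.n_baseline + config.n_post)
    values[: config.n_baseline] = config.basal + noise[: config.n_baseline]
    values[config.n_baseline :] = clean_post + drift + noise[config.n_baseline :]
    return values


def generate_series(
    config: GeneratorConfig,
    kinetics: dict[TissueClass, ClassKinetics] | None = None,
) -> list[AwrfSeries]:
    """Simulate one labeled Awrf trace per case, deterministic given the seed.

    Cases are emitted class by class in the canonical tissue order, so the
    label sequence is a pure function of the class counts.
    """
    kinetics = kinetics if kinetics is not None else DEFAULT_KINETICS
    rng = np.random.default_rng(config.seed)
    out: list[AwrfSeries] = []
    i = 0
    for cls in TissueClass:
        kin = kinetics[cls]
        for _ in range(config.class_counts.get(cls, 0)):
            out.append(
                AwrfSeries(
                    values=_one_series(config, kin, rng),
                    n_baseline=config.n_baseline,
                    case_id=f"case{i:04d}",
                    label=cls.value,
                )
            )
            i += 1
    return out


def class_mean_traces(
    series: list[AwrfSeries],
) -> dict[str, np.ndarray]:
    """Mean raw trace per tissue class."""
    out: dict[str, np.ndarray] = {}
    for cls in TissueClass:
        rows = [s.values for s in series if s.label == cls.value]
        if rows:
            out[cls.value] = np.mean(rows, axis=0)
    return out


# ---------------------------------------------------------------------------
# image-sequence synthesis
# ---------------------------------------------------------------------------


def _smooth_background(shape: tuple[int, int], basal: float, rng: np.random.Generator) -> np.ndarray:
    """Static textured background: basal level plus low-frequency sinusoids.

    The texture makes normalized cross-correlation well-posed (a flat or
    purely linear field would correlate equally at every shift).
    """
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    field = np.zeros(shape)
    # mix of low and mid spatial frequencies: smooth but with enough local
    # gradient that the correlation peak is sharp even when region intensity
    # jumps between frames
    for _ in range(10):
        fr = rng.uniform(1.0, 12.0) / h
        fc = rng.uniform(1.0, 12.0) / w
        amp = rng.uniform(2.0, 5.0)
        ph = rng.uniform(0, 2 * np.pi)
        field += amp * np.sin(2 * np.pi * (fr * rr + fc * cc) + ph)
    return basal + field


def _region_texture(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Static zero-mean texture painted inside a tissue region.

    Exactly zero-mean, so the region's mean intensity per frame stays equal to
    its simulated Awrf value while registration sees sharp structure.
    """
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    tex = np.zeros((height, width))
    for _ in range(4):
        fr = rng.uniform(1.0, 6.0) / height
        fc = rng.uniform(1.0, 6.0) / width
        tex += rng.uniform(1.0, 3.0) * np.sin(2 * np.pi * (fr * rr + fc * cc) + rng.uniform(0, 2 * np.pi))
    return tex - tex.mean()


def generate_image_sequence(
    config: GeneratorConfig,
    kinetics: dict[TissueClass, ClassKinetics] | None = None,
    region_layout: list[tuple[RegionSpec, TissueClass]] | None = None,
    pixel_noise_sd: float = 0.0,
) -> tuple[ImageSequence, np.ndarray, list[AwrfSeries]]:
    """Simulate a jittered colposcopic frame sequence with known shifts.

    Each laid-out region is painted with the intensity of a simulated Awrf
    trace for its class (uniform within the region); the rest of the frame is
    a static smooth textured background.  Consecutive frames are translated by
    integer jitter shifts drawn from N(0, jitter_sd) and rounded.

    Returns the sequence, the ground-truth per-frame shift increments (row 0
    is (0, 0)), and the per-region ground-truth traces.
    """
    kinetics = kinetics if kinetics is not None else DEFAULT_KINETICS
    h, w = config.frame_shape
    if region_layout is None:
        region_layout = [(RegionSpec(h // 2 - 16, w // 2 - 16, 32, 32), TissueClass.HSIL)]
    for spec, _ in region_layout:
        if spec.row < 0 or spec.col < 0 or spec.row + spec.height > h or spec.col + spec.width > w:
            raise ValueError(f"region {spec} outside {h}x{w} frame bounds")
    for i, (a, _) in enumerate(region_layout):
        for b, _ in region_layout[i + 1 :]:
            if not (
                a.row + a.height <= b.row
                or b.row + b.height <= a.row
                or a.col + a.width <= b.col
                or b.col + b.width <= a.col
            ):
                raise ValueError("overlapping regions")

    rng = np.random.default_rng(config.seed)
    n_frames = config.n_baseline + config.n_post

    # per-region traces drawn from the same stream as generate_series would
    # use for a single-class config with this seed
    traces = []
    for idx, (spec, cls) in enumerate(region_layout):
        traces.append(
            AwrfSeries(
                values=_one_series(config, kinetics[TissueClass(cls)], rng),
                n_baseline=config.n_baseline,
                case_id=f"region{idx}",
                label=TissueClass(cls).value,
            )
        )

    shifts = np.zeros((n_frames, 2), dtype=int)
    if config.jitter_sd > 0:
        shifts[1:] = np.rint(rng.normal(0.0, config.jitter_sd, size=(n_frames - 1, 2))).astype(int)
    # a content shift of +s between consecutive frames is realized by moving
    # the crop window by -s over the static scene
    offsets = -np.cumsum(shifts, axis=0)

    margin = int(np.abs(offsets).max()) + 1
    background = _smooth_background((h + 2 * margin, w + 2 * margin), config.basal, rng)
    textures = [_region_texture(spec.height, spec.width, rng) for spec, _ in region_layout]

    frames = np.empty((n_frames, h, w))
    for tix in range(n_frames):
        scene = background.copy()
        for trace, tex, (spec, _) in zip(traces, textures, region_layout):
            r0, c0 = spec.row + margin, spec.col + margin
            scene[r0 : r0 + spec.height, c0 : c0 + spec.width] = trace.values[tix] + tex
        orow, ocol = offsets[tix]
        frames[tix] = scene[
            margin + orow : margin + orow + h, margin + ocol : margin + ocol + w
        ]
        if pixel_noise_sd > 0:
            frames[tix] += rng.normal(0.0, pixel_noise_sd, size=(h, w))

    seq = ImageSequence(frames=frames, frame_period=1.0, n_baseline=config.n_baseline)
    return seq, shifts, traces
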