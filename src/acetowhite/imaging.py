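"""Image-sequence alignment and acetowhite response extraction.

Colposcopic frames drift slightly during acquisition (patient motion:
nervousness, muscle tone, breathing); locally the motion is well modeled as a
pure translation.  Alignment therefore uses normalized cross-correlation
(NCC) of a fixed window between consecutive frames, with an exhaustive
integer-pixel search over a bounded shift range, applied sequentially along
the sequence (frame pairs 1-2, 2-3, ...).  After alignment, a region's Awrf
is simply its mean intensity per frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateWindowError(ValueError):
    """Raised when the correlation window has zero intensity variance."""


@dataclass
class RegionSpec:
    """Axis-aligned rectangle: top-left (row, col), 0-based, half-open."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("region must have positive size")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.height), slice(self.col, self.col + self.width)


@dataclass
class ImageSequence:
    """Ordered stack of same-shape grayscale frames."""

    frames: np.ndarray  # (T, H, W)
    frame_period: float = 1.0
    n_baseline: int = 10

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if len(self.frames) < self.n_baseline + 1:
            raise ValueError("sequence shorter than its baseline segment")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image with ITU-R 601 luma weights; pass gray through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[..., :3] @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"unsupported image shape {image.shape}")


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation (Pearson) of two equal-shape patches.

    Invariant under affine rescaling a*I + b (a > 0) of either patch.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("patches must share a shape")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise DegenerateWindowError("constant-intensity window: NCC undefined")
    return float(da @ db / (na * nb))


def default_window(frame_shape: tuple[int, int]) -> RegionSpec:
    """Central window covering 50% of each frame dimension."""
    h, w = frame_shape
    return RegionSpec(row=h // 4, col=w // 4, height=h // 2, width=w // 2)


def translate(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer translation moving content by (rows, cols); edge-replicated fill."""
    dr, dc = int(shift[0]), int(shift[1])
    h, w = image.shape
    padded = np.pad(image, ((abs(dr), abs(dr)), (abs(dc), abs(dc))), mode="edge")
    return padded[abs(dr) - dr : abs(dr) - dr + h, abs(dc) - dc : abs(dc) - dc + w]


def estimate_shift(
    reference: np.ndarray, moving: np.ndarray, window: RegionSpec, max_shift: int
) -> tuple[int, int]:
    """Integer shift (dr, dc) maximizing window NCC between two frames.

    The returned shift is the displacement of the reference window's content
    within the moving frame: moving[x + s] best matches reference[x] over the
    window.  Exhaustive search on [-max_shift, max_shift]^2; ties are broken
    toward the smallest squared shift magnitude, then row-major order.
    """
    r, c = window.slices()
    ref_patch = reference[r, c]
    h, w = moving.shape
    if (
        window.row - max_shift < 0
        or window.col - max_shift < 0
        or window.row + window.height + max_shift > h
        or window.col + window.width + max_shift > w
    ):
        raise ValueError("window plus max_shift does not fit inside the frame")
    # zero-variance reference window fails fast
    ncc(ref_patch, ref_patch)

    candidates = sorted(
        ((dr, dc) for dr in range(-max_shift, max_shift + 1) for dc in range(-max_shift, max_shift + 1)),
        key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]),
    )
    best, best_val = (0, 0), -np.inf
    for dr, dc in candidates:
        patch = moving[
            window.row + dr : window.row + dr + window.height,
            window.col + dc : window.col + dc + window.width,
        ]
        d = patch - patch.mean()
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        ref_d = ref_patch - ref_patch.mean()
        val = float(ref_d.ravel() @ d.ravel() / (np.linalg.norm(ref_d) * norm))
        if val > best_val:
            best, best_val = (dr, dc), val
    return best


def register_sequence(
    seq: ImageSequence, window: RegionSpec | None = None, max_shift: int = 10
) -> tuple[ImageSequence, np.ndarray]:
    """Sequentially align a sequence by consecutive-pair NCC.

    For each pair (reference = frame i, moving = frame i+1) the best integer
    shift is estimated; shifts are accumulated and each frame is translated by
    the negated cumulative estimate so everything aligns to frame 0.

    Returns the aligned sequence and the per-frame estimated shift increments
    (row 0 is (0, 0)).
    """
    if window is None:
        window = default_window(seq.frame_shape)
    n = len(seq)
    shifts = np.zeros((n, 2), dtype=int)
    for i in range(n - 1):
        shifts[i + 1] = estimate_shift(seq.frames[i], seq.frames[i + 1], window, max_shift)
    offsets = np.cumsum(shifts, axis=0)
    aligned = np.stack(
        [translate(seq.frames[i], (-offsets[i][0], -offsets[i][1])) for i in range(n)]
    )
    return (
        ImageSequence(frames=aligned, frame_period=seq.frame_period, n_baseline=seq.n_baseline),
        shifts,
    )


def extract_awrf(seq: ImageSequence, region: RegionSpec, case_id: str = "", label=None):
    """Mean region intensity per frame: the acetowhite response function."""
    from .datasets import AwrfSeries  # local import to avoid a cycle

    h, w = seq.frame_shape
    if region.row < 0 or region.col < 0 or region.row + region.height > h or region.col + region.width > w:
        raise ValueError(f"region {region} outside {h}x{w} frame bounds")
    r, c = region.slices()
    values = seq.frames[:, r, c].mean(axis=(1, 2))
    return AwrfSeries(values=values, n_baseline=seq.n_baseline, case_id=case_id, label=label)


# ---------------------------------------------------------------------------
# frame directory I/O
# ---------------------------------------------------------------------------


def write_frames(seq: ImageSequence, directory, fmt: str = "png") -> None:
    """Write frames as numbered 8-bit grayscale images (clipped to [0, 255])."""
    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        img = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        iio.imwrite(os.path.join(directory, f"frame{i:04d}.{fmt}"), img)


def read_frames(directory, n_baseline: int = 10, frame_period: float = 1.0) -> ImageSequence:
    """Read an image directory in lexicographic order as a grayscale sequence."""
    import imageio.v3 as iio

    names = sorted(
        f for f in os.listdir(directory) if f.lower().endswith((".png", ".bmp", ".tif", ".tiff"))
    )
    if not names:
        raise ValueError(f"no frames found in {directory}")
    frames = np.stack([to_grayscale(iio.imread(os.path.join(directory, f))) for f in names])
    return ImageSequence(frames=frames, frame_period=frame_period, n_baseline=n_baseline)


def write_shifts_csv(shifts: np.ndarray, path) -> None:
    pd.DataFrame(shifts, columns=["row_shift", "col_shift"]).to_csv(path, index_label="frame")


def read_shifts_csv(path) -> np.ndarray:
    return pd.read_csv(path, index_col="frame")[["row_shift", "col_shift"]].to_numpy(dtype=int)
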