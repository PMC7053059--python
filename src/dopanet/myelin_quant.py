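"""Myelin coverage and sheath thickness from confocal z-stacks.

The pipeline mirrors how mbp:eGFP spinal-cord stacks are scored: maximum
intensity projection across slices, dual-threshold binarization (the same
lower/upper thresholds applied to every embryo), run-length coverage of
myelin-positive columns along the tract, and sheath thickness as the
height of the tight bounding box around the visible myelin. Groups of
embryos are compared with an unpaired t-test on coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MyelinStack",
    "MyelinQuant",
    "max_project",
    "binarize",
    "coverage_along_tract",
    "sheath_thickness",
    "quantify_stack",
    "compare_groups",
]


@dataclass
class MyelinStack:
    """Ordered grayscale slices of equal shape, optional pixel size (µm/px)."""

    slices: np.ndarray  # (z, rows, cols)
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("stack must be a nonempty list of equally shaped 2D slices")
        self.slices = arr

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: Optional[float] = None) -> "MyelinStack":
        import tifffile

        arr = tifffile.imread(str(path))
        return cls(arr, pixel_size)

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.slices.astype(np.float32))


@dataclass
class MyelinQuant:
    coverage_percent: float
    segments: list[tuple[int, int]]  # half-open column intervals
    thickness_px: float = 0.0
    thresholds: tuple[float, float] = (0.0, float("inf"))
    width: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coverage_percent": float(self.coverage_percent),
            "segments": [[int(a), int(b)] for a, b in self.segments],
            "thickness_px": float(self.thickness_px),
            "thresholds": [float(self.thresholds[0]), float(self.thresholds[1])],
            "width": int(self.width),
        }


def max_project(stack: MyelinStack) -> np.ndarray:
    """Pixel-wise maximum intensity projection across slices."""
    return stack.slices.max(axis=0)


def binarize(img: np.ndarray, lower: float, upper: float = float("inf")) -> np.ndarray:
    """True where lower <= pixel <= upper (the dual-threshold myelin mask)."""
    if lower > upper:
        raise ValueError(f"lower threshold {lower} exceeds upper {upper}")
    img = np.asarray(img)
    return (img >= lower) & (img <= upper)


def _runs(col_positive: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], col_positive, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def coverage_along_tract(
    mask: np.ndarray, min_segment_px: int = 1, min_pixels_per_column: int = 1
) -> MyelinQuant:
    """Run-length coverage of myelin-positive columns along the tract.

    A column is myelin-positive when it contains at least
    ``min_pixels_per_column`` true pixels; maximal runs of positive
    columns shorter than ``min_segment_px`` are discarded as speckle.
    Coverage is 100 × (kept run length) / image width.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    col_positive = mask.sum(axis=0) >= min_pixels_per_column
    segments = [
        (s, e) for s, e in _runs(col_positive) if e - s >= min_segment_px
    ]
    width = mask.shape[1]
    covered = sum(e - s for s, e in segments)
    return MyelinQuant(
        coverage_percent=100.0 * covered / width,
        segments=segments,
        width=width,
    )


def sheath_thickness(mask: np.ndarray) -> float:
    """Height (rows) of the tight bounding box around all true pixels.

    For masks with several separated bands the box spans all of them.
    """
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise ValueError("mask has no true pixels; cannot measure thickness")
    return float(rows[-1] - rows[0] + 1)


def quantify_stack(
    stack: MyelinStack,
    lower: float,
    upper: float = float("inf"),
    min_segment_px: int = 1,
) -> MyelinQuant:
    """Project, binarize, and measure coverage + thickness in one call."""
    mask = binarize(max_project(stack), lower, upper)
    quant = coverage_along_tract(mask, min_segment_px=min_segment_px)
    quant.thresholds = (lower, upper)
    quant.thickness_px = sheath_thickness(mask) if mask.any() else 0.0
    return quant


def _coverages(quants: Sequence[MyelinQuant | float]) -> np.ndarray:
    return np.array(
        [q.coverage_percent if isinstance(q, MyelinQuant) else float(q) for q in quants]
    )


def compare_groups(
    quants_a: Sequence[MyelinQuant | float],
    quants_b: Sequence[MyelinQuant | float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Unpaired t-test (Welch by default) on coverage between two groups."""
    a, b = _coverages(quants_a), _coverages(quants_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("both groups have zero variance with different means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
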