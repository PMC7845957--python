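"""Gray-level co-occurrence matrices (GLCM).

A GLCM is a second-order histogram: cell (i, j) counts how often a pixel of
gray level i has a neighbour of gray level j at a fixed (distance, direction)
offset.  Direction offsets follow the common image-axis convention in 0-based
(row, col) coordinates:

    0 degrees   (horizontal)      : ( 0, +d)
    45 degrees  (right diagonal)  : (-d, +d)
    90 degrees  (vertical)        : (-d,  0)
    135 degrees (left diagonal)   : (-d, -d)

In symmetric mode the backward offset is counted as well, which makes the
count matrix equal to its transpose.  Pairs whose neighbour falls outside
the image are skipped (no padding).  Normalising by the grand total yields a
probability matrix P whose cells sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .simulate import SpeckleImage

__all__ = ["DIRECTIONS", "GlcmSpec", "CountMatrix", "GLCM",
           "compute_glcm", "normalize_glcm", "glcm_stack", "glcm_to_csv"]

#: direction (degrees) -> (row, col) unit offset
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

DEFAULT_DISTANCES: tuple[int, ...] = tuple(range(1, 11))
DEFAULT_DIRECTIONS: tuple[int, ...] = (0, 45, 90, 135)


@dataclass(frozen=True)
class GlcmSpec:
    """One co-occurrence configuration: offset distance, direction, depth."""

    distance: int = 1
    direction: int = 0
    levels: int = 256
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {sorted(DIRECTIONS)}, got {self.direction}")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")

    @property
    def offset(self) -> tuple[int, int]:
        dr, dc = DIRECTIONS[self.direction]
        return dr * self.distance, dc * self.distance


@dataclass(frozen=True)
class CountMatrix:
    """Integer co-occurrence counts for one GlcmSpec."""

    counts: np.ndarray
    spec: GlcmSpec

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GLCM:
    """Normalised co-occurrence matrix P; cells sum to one."""

    probabilities: np.ndarray
    spec: GlcmSpec


def _pixels(image: SpeckleImage | np.ndarray) -> np.ndarray:
    pixels = image.pixels if isinstance(image, SpeckleImage) else np.asarray(image)
    if pixels.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.issubdtype(pixels.dtype, np.integer):
        raise ValueError("image must have integer gray levels")
    return pixels


def compute_glcm(image: SpeckleImage | np.ndarray, spec: GlcmSpec) -> CountMatrix:
    """Count ordered gray-level pairs at the spec's offset.

    With ``symmetric`` the backward offset is counted too, so the result is
    exactly its own transpose.
    """
    pixels = _pixels(image)
    levels = spec.levels
    if pixels.max() >= levels:
        raise ValueError(
            f"pixel value {int(pixels.max())} >= levels {levels}")
    rows, cols = pixels.shape
    dr, dc = spec.offset
    if abs(dr) >= rows or abs(dc) >= cols:
        raise ValueError(
            f"offset {spec.offset} does not fit image of shape {pixels.shape}")

    # overlap slices for the forward offset
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    first = pixels[r0:r1, c0:c1].astype(np.int64)
    second = pixels[r0 + dr:r1 + dr, c0 + dc:c1 + dc].astype(np.int64)

    flat = first.ravel() * levels + second.ravel()
    counts = np.bincount(flat, minlength=levels * levels).reshape(levels, levels)
    if spec.symmetric:
        counts = counts + counts.T
    return CountMatrix(counts=counts, spec=spec)


def normalize_glcm(cm: CountMatrix) -> GLCM:
    """Divide every cell by the grand total (fails on an all-zero matrix)."""
    total = cm.total
    if total <= 0:
        raise ValueError("cannot normalise an all-zero count matrix")
    return GLCM(probabilities=cm.counts / total, spec=cm.spec)


def glcm_stack(image: SpeckleImage | np.ndarray,
               distances: Iterable[int] = DEFAULT_DISTANCES,
               directions: Iterable[int] = DEFAULT_DIRECTIONS,
               levels: int = 256,
               symmetric: bool = True) -> Mapping[tuple[int, int], GLCM]:
    """Normalised GLCMs for every (distance, direction) combination.

    The default grid is d = 1..10 by the four directions: 40 matrices.
    """
    stack: dict[tuple[int, int], GLCM] = {}
    for d in distances:
        for theta in directions:
            spec = GlcmSpec(distance=d, direction=theta, levels=levels,
                            symmetric=symmetric)
            stack[(d, theta)] = normalize_glcm(compute_glcm(image, spec))
    return stack


def glcm_to_csv(glcm: GLCM, path) -> None:
    """Dump a GLCM as a dense CSV matrix with gray-level headers."""
    import pandas as pd

    levels = glcm.spec.levels
    frame = pd.DataFrame(glcm.probabilities,
                         index=np.arange(levels), columns=np.arange(levels))
    frame.to_csv(path, index_label="gray")
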