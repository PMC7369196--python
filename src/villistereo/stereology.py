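"""Line-intercept stereology of pericyte coverage.

The fraction of the capillary abluminal (basal) surface covered by
pericytes is estimated with randomly offset grids: every ``slice_stride``-th
slice receives a grid of ``n_lines`` equally spaced horizontal lines at a
random common offset, each line is walked left to right, every transition
between endothelial wall and a non-wall, non-lumen voxel is a capillary
basal-membrane intersect, and the intersect is a pericyte intersect when the
voxel immediately abluminal of the crossing is pericyte.  The coverage
estimate is the ratio of pericyte to capillary intersects, with a running
(cumulative) mean over sampled slices to judge sampling adequacy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .labels import LabelStack, Role

__all__ = [
    "GridSpec",
    "CoverageEstimate",
    "make_offset_grid",
    "count_line_intersections",
    "estimate_coverage",
]

DEFAULT_N_LINES = 4
DEFAULT_SLICE_STRIDE = 50


@dataclass(frozen=True)
class GridSpec:
    """A randomly offset square grid for one slice.

    Only the horizontal lines (rows) are counted; the vertical line columns
    are kept for drawing overlays.
    """

    image_shape: tuple[int, int]
    n_lines: int
    offset_rows: tuple[int, ...]
    offset_cols: tuple[int, ...]
    slice_stride: int = DEFAULT_SLICE_STRIDE

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if self.n_lines < 1:
            raise ValueError("need at least one line")
        if self.slice_stride < 1:
            raise ValueError("slice_stride must be >= 1")
        if any(not 0 <= r < h for r in self.offset_rows):
            raise ValueError("row offsets must lie within the image height")
        if any(not 0 <= c < w for c in self.offset_cols):
            raise ValueError("column offsets must lie within the image width")


def make_offset_grid(
    image_height: int,
    image_width: int,
    n_lines: int = DEFAULT_N_LINES,
    rng_seed: int | np.random.Generator = 0,
    slice_stride: int = DEFAULT_SLICE_STRIDE,
) -> GridSpec:
    """Equally spaced lines with a uniform random offset.

    Line spacing is ``image_height / n_lines``; the offset is drawn
    uniformly from ``[0, spacing)`` so every row has equal sampling
    probability (the unbiasedness requirement of line-intercept counting).
    """
    if image_height < n_lines or image_width < n_lines:
        raise ValueError("image dimensions must be at least n_lines")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    spacing_r = image_height / n_lines
    spacing_c = image_width / n_lines
    off_r = rng.uniform(0.0, spacing_r)
    off_c = rng.uniform(0.0, spacing_c)
    rows = tuple(
        min(int(math.floor(off_r + k * spacing_r)), image_height - 1)
        for k in range(n_lines)
    )
    cols = tuple(
        min(int(math.floor(off_c + k * spacing_c)), image_width - 1)
        for k in range(n_lines)
    )
    return GridSpec(
        image_shape=(image_height, image_width),
        n_lines=n_lines,
        offset_rows=rows,
        offset_cols=cols,
        slice_stride=slice_stride,
    )


def count_line_intersections(
    slice_labels: np.ndarray,
    grid: GridSpec,
    semantics: Mapping[int, Role],
    abluminal_gap_voxels: int = 0,
    _lut: np.ndarray | None = None,
) -> tuple[int, int]:
    """Count basal-membrane and pericyte intersects on one slice.

    Walking each horizontal grid line left to right, a capillary intersect
    is every transition between a wall voxel (endothelium or IEP) and an
    abluminal voxel (anything that is neither wall nor lumen); tangential
    grazes count once per entry and once per exit.  A pericyte intersect is
    a capillary intersect whose first abluminal voxel is pericyte; with
    ``abluminal_gap_voxels = g > 0`` a pericyte up to ``g`` voxels further
    out (e.g. across a thin basement-membrane gap) also counts.

    Returns ``(capillary_hits, pericyte_hits)``.  A slice with no
    endothelial label yields ``(0, 0)`` with a warning.
    """
    if _lut is None:
        _lut = _semantics_lut(slice_labels, semantics)
    codes = _lut[slice_labels]
    if not (codes == 1).any():
        warnings.warn("slice contains no endothelial voxels", stacklevel=2)
        return 0, 0
    cap = 0
    per = 0
    for row in grid.offset_rows:
        line = codes[row]
        wall = line == 1
        abl = (line != 1) & (line != 2)
        # wall -> abluminal exits
        exit_at = np.flatnonzero(wall[:-1] & abl[1:])
        # abluminal -> wall entries
        entry_at = np.flatnonzero(abl[:-1] & wall[1:])
        cap += exit_at.size + entry_at.size
        for idx, step in ((exit_at + 1, 1), (entry_at, -1)):
            for i in idx:
                for g in range(abluminal_gap_voxels + 1):
                    j = i + step * g
                    if not 0 <= j < line.size or not abl[j]:
                        break
                    if line[j] == 3:
                        per += 1
                        break
    return cap, per


def _semantics_lut(labels: np.ndarray, semantics: Mapping[int, Role]) -> np.ndarray:
    top = int(labels.max())
    lut = np.zeros(top + 1, dtype=np.uint8)
    for lab, role in semantics.items():
        if lab > top:
            continue
        if role.kind in ("endothelial_cell", "iep"):
            lut[lab] = 1
        elif role.kind == "lumen":
            lut[lab] = 2
        elif role.kind == "pericyte":
            lut[lab] = 3
    return lut


@dataclass
class CoverageEstimate:
    """Aggregated intersect counts and the pericyte/capillary ratio.

    ``ratio`` is ``None`` (undefined, never zero) when no capillary
    intersect was sampled.  ``running_means`` holds the cumulative ratio
    after each sampled slice; its final element equals ``ratio``.
    """

    n_capillary_intersects: int
    n_pericyte_intersects: int
    per_slice: list[tuple[int, int, int]]  # (slice index, capillary, pericyte)
    slice_stride: int
    n_lines: int
    rng_seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_pericyte_intersects <= self.n_capillary_intersects:
            raise ValueError("pericyte intersects must not exceed capillary intersects")

    @property
    def ratio(self) -> float | None:
        if self.n_capillary_intersects == 0:
            return None
        return self.n_pericyte_intersects / self.n_capillary_intersects

    @property
    def running_means(self) -> list[float | None]:
        out: list[float | None] = []
        cap = per = 0
        for _, c, p in self.per_slice:
            cap += c
            per += p
            out.append(per / cap if cap else None)
        return out

    def to_dict(self) -> dict:
        return {
            "n_capillary_intersects": self.n_capillary_intersects,
            "n_pericyte_intersects": self.n_pericyte_intersects,
            "ratio": self.ratio,
            "running_means": self.running_means,
            "per_slice": [list(t) for t in self.per_slice],
            "slice_stride": self.slice_stride,
            "n_lines": self.n_lines,
            "rng_seed": self.rng_seed,
        }


def estimate_coverage(
    stack: LabelStack,
    slice_stride: int = DEFAULT_SLICE_STRIDE,
    n_lines: int = DEFAULT_N_LINES,
    rng_seed: int = 0,
    abluminal_gap_voxels: int = 0,
) -> CoverageEstimate:
    """Grid line-intercept estimate of pericyte coverage for a whole stack.

    Slices ``0, stride, 2*stride, ...`` are sampled, each with a freshly
    offset grid (per-slice offsets lower the variance relative to a single
    offset for the whole stack); counts are pooled and the cumulative ratio
    recorded per sampled slice.
    """
    if slice_stride < 1:
        raise ValueError("slice_stride must be >= 1")
    if stack.n_slices < 1:
        raise ValueError("stack has no slices")
    rng = np.random.default_rng(rng_seed)
    h, w = stack.shape[1:]
    lut = _semantics_lut(stack.voxels, stack.semantics)
    per_slice = []
    cap_total = per_total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty slices are legitimate here
        for z in range(0, stack.n_slices, slice_stride):
            grid = make_offset_grid(h, w, n_lines, rng, slice_stride)
            cap, per = count_line_intersections(
                stack.voxels[z], grid, stack.semantics,
                abluminal_gap_voxels=abluminal_gap_voxels, _lut=lut,
            )
            cap_total += cap
            per_total += per
            per_slice.append((z, cap, per))
    return CoverageEstimate(
        n_capillary_intersects=cap_total,
        n_pericyte_intersects=per_total,
        per_slice=per_slice,
        slice_stride=slice_stride,
        n_lines=n_lines,
        rng_seed=rng_seed,
    )
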