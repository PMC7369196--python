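"""Per-slice vessel cross-section analysis.

For each (sampled) slice of a segmented vessel this module counts the
endothelial junctions around the ring (for a closed ring of k >= 2 cells the
number of cell-cell seams equals the number of distinct cells), measures the
widest-point (Feret) diameter of the outer endothelial boundary, classifies
dilated profiles against a diameter threshold, guards against partial
profiles created by taking the edge off one side of a vessel, and summarises
subsampled arteriole/venule series as mean +/- SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .labels import LabelStack, Role

__all__ = [
    "CapillaryProfile",
    "VesselSummary",
    "RingNotClosedError",
    "junction_count",
    "profile_diameter",
    "is_full_profile",
    "classify_dilated",
    "capillary_profiles",
    "vessel_series_summary",
    "DEFAULT_DILATED_THRESHOLD_UM",
]

#: Diameter above which a capillary profile is classed as dilated (um);
#: exactly-threshold profiles are non-dilated (strict inequality).
DEFAULT_DILATED_THRESHOLD_UM = 11.0

_CROSS2D = ndimage.generate_binary_structure(2, 1)
_BOX2D = ndimage.generate_binary_structure(2, 2)


class RingNotClosedError(ValueError):
    """The endothelial ring around the lumen is not closed in this slice."""


@dataclass(frozen=True)
class CapillaryProfile:
    """One full-vessel cross-section."""

    slice_index: int
    vessel_id: int
    full_profile: bool
    junction_count: int | None = None
    diameter_um: float | None = None
    dilated: bool | None = None

    def to_dict(self) -> dict:
        return {
            "slice_index": self.slice_index,
            "vessel_id": self.vessel_id,
            "full_profile": self.full_profile,
            "junction_count": self.junction_count,
            "diameter_um": self.diameter_um,
            "dilated": self.dilated,
        }


@dataclass(frozen=True)
class VesselSummary:
    """Mean +/- SD of diameter and junction count over sampled slices."""

    vessel_id: int
    mean_diameter_um: float
    sd_diameter_um: float
    mean_junctions: float
    sd_junctions: float
    n_observations: int
    diameters_um: tuple[float, ...] = ()
    junctions: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "vessel_id": self.vessel_id,
            "mean_diameter_um": self.mean_diameter_um,
            "sd_diameter_um": self.sd_diameter_um,
            "mean_junctions": self.mean_junctions,
            "sd_junctions": self.sd_junctions,
            "n_observations": self.n_observations,
            "diameters_um": list(self.diameters_um),
            "junctions": list(self.junctions),
        }


def _kind_labels(semantics: Mapping[int, Role], *kinds: str, vessel=None) -> list[int]:
    return sorted(
        lab
        for lab, role in semantics.items()
        if role.kind in kinds and (vessel is None or role.vessel == vessel)
    )


def junction_count(
    slice_labels: np.ndarray,
    lumen_label: int,
    semantics: Mapping[int, Role],
) -> int:
    """Number of endothelial junctions around a closed ring.

    Traverses the ring of endothelial voxels surrounding the lumen and
    returns the number of distinct endothelial cells encountered, which for
    a closed ring of k >= 2 cells equals the number of cell-cell junction
    seams.  A single-cell ring returns 1 (whether its longitudinal seam is
    present cannot be told from ids).  Raises :class:`RingNotClosedError`
    when the lumen touches a non-wall label or the image border.
    """
    lumen = slice_labels == lumen_label
    if not lumen.any():
        raise RingNotClosedError("lumen label absent from slice")
    if (
        lumen[0].any() or lumen[-1].any() or lumen[:, 0].any() or lumen[:, -1].any()
    ):
        raise RingNotClosedError("lumen touches the image border")
    wall_labels = _kind_labels(semantics, "endothelial_cell", "iep")
    halo = ndimage.binary_dilation(lumen, structure=_CROSS2D) & ~lumen
    halo_vals = slice_labels[halo]
    if not np.isin(halo_vals, wall_labels).all():
        raise RingNotClosedError("lumen touches a non-endothelial label")
    ring = ndimage.binary_dilation(lumen, structure=_BOX2D) & ~lumen
    ring_vals = slice_labels[ring]
    cell_ids = {
        semantics[int(v)].cell
        for v in np.unique(ring_vals)
        if int(v) in semantics and semantics[int(v)].kind == "endothelial_cell"
    }
    if not cell_ids:
        raise RingNotClosedError("no endothelial cells adjacent to the lumen")
    return len(cell_ids)


def profile_diameter(
    slice_labels: np.ndarray,
    vessel_id: int,
    spacing_nm: Sequence[float],
    semantics: Mapping[int, Role],
    surface: str = "abluminal",
) -> float:
    """Widest-point (maximum Feret) extent of a vessel cross-section, in um.

    By default the outer (abluminal) endothelial boundary is measured;
    ``surface="lumen"`` measures the lumen instead.  Voxel extent is
    honoured by adding the mean in-plane spacing to the largest
    centre-to-centre distance, so a single-voxel object reports one pixel.
    """
    dz_dy_dx = tuple(float(s) for s in spacing_nm)
    dy, dx = dz_dy_dx[-2], dz_dy_dx[-1]
    if surface == "abluminal":
        labs = _kind_labels(
            semantics, "lumen", "endothelial_cell", "iep", vessel=vessel_id
        )
    elif surface == "lumen":
        labs = _kind_labels(semantics, "lumen", vessel=vessel_id)
    else:
        raise ValueError("surface must be 'abluminal' or 'lumen'")
    mask = np.isin(slice_labels, labs)
    if not mask.any():
        raise ValueError(f"vessel {vessel_id} absent from slice")
    boundary = mask & ~ndimage.binary_erosion(mask, structure=_CROSS2D)
    pts = np.argwhere(boundary).astype(float)
    pts[:, 0] *= dy
    pts[:, 1] *= dx
    return (_max_caliper(pts) + (dy + dx) / 2.0) / 1000.0


def _max_caliper(pts: np.ndarray) -> float:
    """Largest pairwise distance, via the convex hull when possible."""
    if len(pts) == 1:
        return 0.0
    if len(pts) > 10:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) point sets: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).max())


def classify_dilated(
    diameter_um: float,
    threshold_um: float = DEFAULT_DILATED_THRESHOLD_UM,
) -> bool:
    """Dilated iff strictly wider than the threshold (default 11 um)."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return diameter_um > threshold_um


def is_full_profile(
    stack: LabelStack,
    slice_index: int,
    vessel_id: int,
    sliver_fraction: float = 0.5,
    _lumen_mask: np.ndarray | None = None,
) -> bool:
    """Whether a slice shows a full vessel cross-section.

    Mirrors the inspection of regions above and below a profile: the first
    and last slices can never be verified and are excluded by rule; the
    lumen must be present and overlap its counterpart in both adjacent
    slices; the vessel must not touch the lateral image border; and a slice
    whose lumen area lies on a monotone run vanishing to zero while well
    below the vessel's typical area (under ``sliver_fraction`` of the median
    positive area) is a grazed edge, not a full profile.
    """
    z = slice_index
    if z <= 0 or z >= stack.n_slices - 1:
        return False
    lum = stack.mask("lumen", vessel=vessel_id) if _lumen_mask is None else _lumen_mask
    areas = lum.reshape(stack.n_slices, -1).sum(axis=1)
    if areas[z] == 0 or areas[z - 1] == 0 or areas[z + 1] == 0:
        return False
    if not (lum[z] & lum[z - 1]).any() or not (lum[z] & lum[z + 1]).any():
        return False
    wall = np.isin(
        stack.voxels[z],
        _kind_labels(stack.semantics, "lumen", "endothelial_cell", "iep",
                     vessel=vessel_id),
    )
    if wall[0].any() or wall[-1].any() or wall[:, 0].any() or wall[:, -1].any():
        return False
    median_area = float(np.median(areas[areas > 0]))
    if areas[z] < sliver_fraction * median_area:
        if _monotone_vanishes(areas, z, +1) or _monotone_vanishes(areas, z, -1):
            return False
    return True


def _monotone_vanishes(areas: np.ndarray, z: int, step: int) -> bool:
    """True when areas run non-increasing from z to a zero inside the stack."""
    prev = areas[z]
    i = z + step
    while 0 <= i < len(areas):
        if areas[i] > prev:
            return False
        if areas[i] == 0:
            return True
        prev = areas[i]
        i += step
    return False


def capillary_profiles(
    stack: LabelStack,
    vessel_id: int = 1,
    slice_stride: int = 1,
    dilated_threshold_um: float = DEFAULT_DILATED_THRESHOLD_UM,
) -> list[CapillaryProfile]:
    """Profile table for every sampled slice of one vessel."""
    lumen_labels = _kind_labels(stack.semantics, "lumen", vessel=vessel_id)
    if not lumen_labels:
        raise ValueError(f"no lumen label for vessel {vessel_id}")
    lum = stack.mask("lumen", vessel=vessel_id)
    out = []
    for z in range(0, stack.n_slices, slice_stride):
        full = is_full_profile(stack, z, vessel_id, _lumen_mask=lum)
        junctions = None
        diameter = None
        dilated = None
        if lum[z].any():
            try:
                junctions = junction_count(
                    stack.voxels[z], lumen_labels[0], stack.semantics
                )
            except RingNotClosedError:
                full = False
            try:
                diameter = profile_diameter(
                    stack.voxels[z], vessel_id, stack.spacing_nm, stack.semantics
                )
            except ValueError:
                diameter = None
            if full and diameter is not None:
                dilated = classify_dilated(diameter, dilated_threshold_um)
        out.append(
            CapillaryProfile(
                slice_index=z,
                vessel_id=vessel_id,
                full_profile=full,
                junction_count=junctions,
                diameter_um=diameter,
                dilated=dilated,
            )
        )
    return out


def vessel_series_summary(
    stack: LabelStack,
    vessel_id: int,
    slice_stride: int = 25,
) -> VesselSummary:
    """Mean +/- SD diameter and junction count, sampling every n-th slice.

    Used for the arteriole/venule series: the widest point and the ring
    cell count are measured in every ``slice_stride``-th cross-section and
    averaged.  SDs are sample (n-1) SDs; a single observation reports 0.
    """
    if slice_stride < 1:
        raise ValueError("slice_stride must be >= 1")
    lumen_labels = _kind_labels(stack.semantics, "lumen", vessel=vessel_id)
    if not lumen_labels:
        raise ValueError(f"no lumen label for vessel {vessel_id}")
    diameters = []
    junctions = []
    for z in range(0, stack.n_slices, slice_stride):
        sl = stack.voxels[z]
        if not (sl == lumen_labels[0]).any():
            continue
        diameters.append(
            profile_diameter(sl, vessel_id, stack.spacing_nm, stack.semantics)
        )
        junctions.append(junction_count(sl, lumen_labels[0], stack.semantics))
    if not diameters:
        raise ValueError(f"vessel {vessel_id} absent from every sampled slice")
    d = np.asarray(diameters)
    j = np.asarray(junctions, dtype=float)
    sd = lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0
    return VesselSummary(
        vessel_id=vessel_id,
        mean_diameter_um=float(d.mean()),
        sd_diameter_um=sd(d),
        mean_junctions=float(j.mean()),
        sd_junctions=sd(j),
        n_observations=len(diameters),
        diameters_um=tuple(float(x) for x in d),
        junctions=tuple(int(x) for x in junctions),
    )
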