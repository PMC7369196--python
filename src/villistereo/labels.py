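"""Shared containers for segmented label volumes.

A :class:`LabelStack` is the universal input of the pipeline: a 3D integer
array indexed ``(slice z, row y, column x)`` with anisotropic physical voxel
spacing ``(dz, dy, dx)`` in nanometres, plus a semantics map assigning every
integer label a tissue role (intervillous space, syncytiotrophoblast, stroma,
capillary lumen, an individual endothelial cell, pericyte, or an individual
interendothelial protrusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = ["Role", "LabelStack", "KINDS", "WALL_KINDS"]

#: Recognised tissue roles.
KINDS = frozenset(
    {
        "intervillous_space",
        "syncytiotrophoblast",
        "stroma",
        "lumen",
        "endothelial_cell",
        "pericyte",
        "iep",
    }
)

#: Kinds that count as endothelial wall tissue when tracing the abluminal
#: (basal) surface: IEPs sit inside the wall, enclosed by endothelial
#: cytoplasm, so they are wall tissue for surface purposes.
WALL_KINDS = ("endothelial_cell", "iep")


@dataclass(frozen=True)
class Role:
    """Semantic role of one integer label.

    ``vessel`` groups labels belonging to the same vessel (lumen plus its
    endothelial ring); ``cell`` identifies an individual endothelial cell and
    ``iep`` an individual interendothelial protrusion.
    """

    kind: str
    vessel: int | None = None
    cell: int | None = None
    iep: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown role kind {self.kind!r}")
        if self.kind == "endothelial_cell" and self.cell is None:
            raise ValueError("endothelial_cell role needs a cell id")
        if self.kind == "iep" and self.iep is None:
            raise ValueError("iep role needs an iep id")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        for k in ("vessel", "cell", "iep"):
            v = getattr(self, k)
            if v is not None:
                d[k] = int(v)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Role":
        return cls(
            kind=d["kind"],
            vessel=d.get("vessel"),
            cell=d.get("cell"),
            iep=d.get("iep"),
        )


@dataclass
class LabelStack:
    """3D integer label volume with physical voxel spacing.

    Parameters
    ----------
    voxels
        Integer array of shape ``(n_slices, height, width)``.
    spacing_nm
        ``(dz, dy, dx)`` physical voxel spacing in nanometres.
    semantics
        Mapping from integer label to :class:`Role`.
    """

    voxels: np.ndarray
    spacing_nm: tuple[float, float, float]
    semantics: dict[int, Role] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must be an integer array")
        self.spacing_nm = tuple(float(s) for s in self.spacing_nm)
        if len(self.spacing_nm) != 3 or any(s <= 0 for s in self.spacing_nm):
            raise ValueError("spacing_nm must be three positive lengths")
        self.semantics = {int(k): v for k, v in self.semantics.items()}

    # -- basic geometry ----------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def axial_extent_um(self) -> float:
        """Axial extent ``n_slices x dz`` in micrometres."""
        return self.n_slices * self.spacing_nm[0] / 1000.0

    # -- semantics ---------------------------------------------------------
    def validate(self) -> None:
        """Fail loudly if any label present lacks a semantics entry."""
        missing = [v for v in self.label_counts() if v not in self.semantics]
        if missing:
            raise ValueError(f"labels without semantics entries: {missing}")

    def labels_of(self, *kinds: str, vessel: int | None = None) -> list[int]:
        """Labels whose role kind is in ``kinds`` (optionally one vessel)."""
        out = []
        for lab, role in self.semantics.items():
            if role.kind in kinds and (vessel is None or role.vessel == vessel):
                out.append(lab)
        return sorted(out)

    def mask(self, *kinds: str, vessel: int | None = None) -> np.ndarray:
        """Boolean mask of all voxels whose role kind is in ``kinds``."""
        labs = self.labels_of(*kinds, vessel=vessel)
        if not labs:
            return np.zeros(self.shape, dtype=bool)
        # lookup-table indexing beats np.isin by an order of magnitude on
        # large volumes of small integer labels
        top = int(self.voxels.max())
        lut = np.zeros(top + 1, dtype=bool)
        for lab in labs:
            if lab <= top:
                lut[lab] = True
        return lut[self.voxels]

    def class_lut(self, max_label: int | None = None) -> np.ndarray:
        """Lookup table label -> coarse class code.

        Codes: 0 other (abluminal candidate), 1 wall (endothelium or IEP),
        2 lumen, 3 pericyte.  Pericyte is also an abluminal candidate; the
        code distinguishes it so intercept counting can attribute hits.
        """
        top = int(self.voxels.max()) if max_label is None else max_label
        lut = np.zeros(top + 1, dtype=np.uint8)
        for lab, role in self.semantics.items():
            if lab > top:
                continue
            if role.kind in WALL_KINDS:
                lut[lab] = 1
            elif role.kind == "lumen":
                lut[lab] = 2
            elif role.kind == "pericyte":
                lut[lab] = 3
        return lut

    def label_counts(self) -> dict[int, int]:
        if np.issubdtype(self.voxels.dtype, np.unsignedinteger):
            counts = np.bincount(self.voxels.ravel())
            return {int(l): int(c) for l, c in enumerate(counts) if c > 0}
        labs, counts = np.unique(self.voxels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts)}
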