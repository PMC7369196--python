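"""Readers and writers binding the pipeline together.

Label stacks travel as multipage TIFF (one page per slice, 16-bit unsigned,
uncompressed for byte-exact round trips) plus a JSON sidecar carrying the
physical voxel spacing, the label semantics, provenance and optionally the
phantom ground truth.  Voxel coordinates are 0-based ``(z, y, x)`` indices
everywhere; physical units appear only in outputs.  A stack without a
sidecar is an error -- spacing is never silently guessed.

Annotation tables of protrusion tip/base coordinates are CSV with columns
``iep_id, placenta_id, base_z, base_y, base_x, tip_z, tip_y, tip_x,
width_nm, branched``; duplicate ids are rejected (the double-counting
guard of the manual marking workflow).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .labels import LabelStack, Role
from .morphometry import IEPRecord
from .phantom import PhantomTruth

__all__ = [
    "write_stack",
    "read_stack",
    "read_truth",
    "read_annotations",
    "write_annotations",
    "ANNOTATION_COLUMNS",
]

ANNOTATION_COLUMNS = [
    "iep_id",
    "placenta_id",
    "base_z",
    "base_y",
    "base_x",
    "tip_z",
    "tip_y",
    "tip_x",
    "width_nm",
    "branched",
]

_COORD_CONVENTION = "0-based (z, y, x) voxel indices; z increases with page order"


def _sidecar_path(tiff_path) -> Path:
    return Path(str(tiff_path) + ".json")


def write_stack(
    stack: LabelStack,
    tiff_path,
    sidecar_path=None,
    truth: PhantomTruth | None = None,
    provenance: dict | None = None,
) -> None:
    """Write a label stack as multipage TIFF plus JSON sidecar."""
    stack.validate()
    if stack.voxels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed the 16-bit range")
    tifffile.imwrite(
        str(tiff_path),
        stack.voxels.astype(np.uint16),
        photometric="minisblack",
    )
    sidecar = {
        "spacing_nm": list(stack.spacing_nm),
        "semantics": {str(lab): role.to_dict() for lab, role in stack.semantics.items()},
        "coordinate_convention": _COORD_CONVENTION,
        "n_slices": stack.n_slices,
        "axial_extent_um": stack.axial_extent_um(),
        "provenance": provenance,
        "truth": truth.to_dict() if truth is not None else None,
    }
    path = _sidecar_path(tiff_path) if sidecar_path is None else Path(sidecar_path)
    with open(path, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_stack(tiff_path, sidecar_path=None) -> LabelStack:
    """Read a label stack; the sidecar is mandatory.

    Labels present in the volume but absent from the sidecar semantics are
    a hard error listing the offenders.
    """
    path = _sidecar_path(tiff_path) if sidecar_path is None else Path(sidecar_path)
    if not path.exists():
        raise FileNotFoundError(
            f"sidecar {path} not found: voxel spacing and label semantics are "
            "required and are never guessed"
        )
    with open(path) as fh:
        sidecar = json.load(fh)
    voxels = tifffile.imread(str(tiff_path))
    if voxels.ndim == 2:
        voxels = voxels[None]
    if voxels.ndim != 3:
        raise ValueError(f"expected a multipage 2D TIFF, got ndim={voxels.ndim}")
    semantics = {
        int(lab): Role.from_dict(d) for lab, d in sidecar["semantics"].items()
    }
    stack = LabelStack(
        voxels=voxels,
        spacing_nm=tuple(sidecar["spacing_nm"]),
        semantics=semantics,
    )
    stack.validate()
    return stack


def read_truth(tiff_path, sidecar_path=None) -> PhantomTruth | None:
    """Read the phantom ground truth from a sidecar, if recorded."""
    from .morphometry import ProtrusionClass

    path = _sidecar_path(tiff_path) if sidecar_path is None else Path(sidecar_path)
    with open(path) as fh:
        sidecar = json.load(fh)
    t = sidecar.get("truth")
    if t is None:
        return None
    records = [
        IEPRecord(
            iep_id=r["iep_id"],
            base=tuple(r["base"]),
            tip=tuple(r["tip"]),
            width_nm=r["width_nm"],
            donor_cell=r.get("donor_cell"),
            acceptor_cell=r.get("acceptor_cell"),
            branched=r.get("branched", False),
            length_nm=r.get("length_nm"),
            cls=ProtrusionClass(r["cls"]) if r.get("cls") else None,
        )
        for r in t["iep_records"]
    ]
    return PhantomTruth(
        true_pericyte_fraction=t["true_pericyte_fraction"],
        iep_records=records,
        cells_per_slice=t["cells_per_slice"],
        true_diameter_per_slice=t["true_diameter_per_slice"],
        total_tissue_volume_nm3=t["total_tissue_volume_nm3"],
        pericyte_fraction_unreachable=t.get("pericyte_fraction_unreachable", False),
    )


class AnnotationError(ValueError):
    pass


def read_annotations(
    csv_path,
    stack_shape: tuple[int, int, int] | None = None,
) -> list[IEPRecord]:
    """Read a protrusion annotation table.

    Validates the header, uniqueness of ``iep_id`` (double-counting guard),
    positive widths and -- when ``stack_shape`` is given -- coordinate
    bounds, reporting offending rows by number (1-based, excluding the
    header).
    """
    df = pd.read_csv(csv_path, dtype={"placenta_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")
    problems: list[str] = []
    seen: dict[int, int] = {}
    records: list[IEPRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        iep_id = int(row.iep_id)
        if iep_id in seen:
            problems.append(
                f"row {i}: duplicate iep_id {iep_id} (first seen at row {seen[iep_id]})"
            )
            continue
        seen[iep_id] = i
        base = (int(row.base_z), int(row.base_y), int(row.base_x))
        tip = (int(row.tip_z), int(row.tip_y), int(row.tip_x))
        if row.width_nm <= 0:
            problems.append(f"row {i}: non-positive width {row.width_nm}")
            continue
        if stack_shape is not None:
            for name, coord in (("base", base), ("tip", tip)):
                if any(not 0 <= c < s for c, s in zip(coord, stack_shape)):
                    problems.append(
                        f"row {i}: {name} coordinate {coord} outside stack "
                        f"shape {tuple(stack_shape)}"
                    )
        placenta = None if pd.isna(row.placenta_id) else str(row.placenta_id)
        records.append(
            IEPRecord(
                iep_id=iep_id,
                base=base,
                tip=tip,
                width_nm=float(row.width_nm),
                branched=bool(int(row.branched)),
                placenta_id=placenta,
            )
        )
    if problems:
        raise AnnotationError("invalid annotation table:\n" + "\n".join(problems))
    return records


def write_annotations(records: Sequence[IEPRecord], csv_path) -> None:
    rows = [
        {
            "iep_id": r.iep_id,
            "placenta_id": r.placenta_id if r.placenta_id is not None else "",
            "base_z": r.base[0],
            "base_y": r.base[1],
            "base_x": r.base[2],
            "tip_z": r.tip[0],
            "tip_y": r.tip[1],
            "tip_x": r.tip[2],
            "width_nm": r.width_nm,
            "branched": int(r.branched),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(csv_path, index=False)
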