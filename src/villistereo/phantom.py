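"""Synthetic phantoms of villous microvessels with known ground truth.

The generator builds seeded 3D label volumes emulating segmented serial
block-face SEM stacks of placental terminal-villus capillaries (and, at
coarser spacing, intermediate-villus arterioles/venules): a lumen tube runs
through the stack, wrapped by a closed endothelial ring partitioned into
longitudinally wandering cell sectors, surrounded by stroma, a
syncytiotrophoblast shell and intervillous space.  Pericytes are laid down
as longitudinal, gently helical processes on the abluminal surface whose
width is scaled so the realised covered fraction of abluminal voxel faces
matches a requested target.  Interendothelial protrusions are carved as
capsules rooted on a junction line and protruding into the adjacent cell.

Every stochastic choice derives from one root seed through named
sub-streams, so e.g. adding protrusions does not perturb pericyte placement,
and identical configurations are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .labels import LabelStack, Role, WALL_KINDS
from .morphometry import IEPRecord, chord_length, classify_protrusion

__all__ = [
    "IepSpec",
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "true_surface_coverage",
    "arteriole_venule_phantoms",
    "PhantomSpecError",
    "EmptyVesselError",
    "L_IVS",
    "L_STB",
    "L_STROMA",
    "L_PERICYTE",
    "L_LUMEN",
]

# Fixed labels of the non-cellular compartments; endothelial cells are
# numbered from FIRST_CELL_LABEL and protrusions from FIRST_IEP_LABEL.
L_IVS = 0
L_STB = 1
L_STROMA = 2
L_PERICYTE = 3
L_LUMEN = 4
FIRST_CELL_LABEL = 10
FIRST_IEP_LABEL = 1000


class PhantomSpecError(ValueError):
    """A requested geometric feature cannot be realised."""


class EmptyVesselError(ValueError):
    """The stack contains no endothelial voxels."""


@dataclass(frozen=True)
class IepSpec:
    """Requested interendothelial protrusion.

    ``donor_cell`` is the angular-sector index of the donor endothelial cell
    (at the base slice); ``junction_pos`` the fractional axial position of
    the base in [0, 1].
    """

    length_um: float
    width_um: float
    donor_cell: int = 0
    junction_pos: float = 0.5
    branched: bool = False

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0:
            raise ValueError("IEP length and width must be positive")
        if self.length_um <= self.width_um:
            raise ValueError("IEP length must exceed its width")
        if not 0.0 <= self.junction_pos <= 1.0:
            raise ValueError("junction_pos must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of a single-vessel phantom.

    Defaults emulate the terminal-villus capillary stacks being quantified:
    a 256 x 256 x 400 volume at (50, 25, 25) nm spacing, a 5.0 um diameter
    capillary lined by five endothelial cells with sinusoidally wandering
    junction lines, and pericytes covering 15% of the abluminal surface.
    """

    n_slices: int = 400
    image_shape: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 25.0
    slice_thickness_nm: float = 50.0
    #: (slice index, outer endothelial radius in um) anchors, linearly
    #: interpolated between and held constant beyond.
    capillary_radius_profile: tuple[tuple[int, float], ...] = ((0, 2.5),)
    n_endothelial_cells: int = 5
    wall_thickness_um: float = 0.8
    pericyte_target_fraction: float = 0.15
    pericyte_thickness_um: float = 0.25
    n_pericyte_processes: int = 8
    #: total helical twist (radians) of each pericyte process over the stack
    pericyte_twist_rad: float = math.pi
    villus_radius_um: float | None = None
    stb_thickness_um: float = 0.2
    #: junction wander amplitude as a fraction of the cell angular width
    junction_wander_amplitude: float = 0.2
    junction_wander_period_um: float = 10.0
    iep_specs: tuple[IepSpec, ...] = ()
    #: tangential tilt of IEP axes (dimensionless slope versus axial)
    iep_tilt: float = 0.15
    #: optional per-slice endothelial cell count anchors (slice, count),
    #: piecewise constant; overrides n_endothelial_cells when given
    cell_count_schedule: tuple[tuple[int, int], ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("need at least two slices")
        for name in (
            "pixel_size_nm",
            "slice_thickness_nm",
            "wall_thickness_um",
            "pericyte_thickness_um",
            "stb_thickness_um",
            "junction_wander_period_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.pericyte_target_fraction <= 1.0:
            raise ValueError("pericyte_target_fraction must lie in [0, 1]")
        if not self.capillary_radius_profile:
            raise ValueError("capillary_radius_profile needs at least one anchor")
        if any(r <= 0 for _, r in self.capillary_radius_profile):
            raise ValueError("radii must be positive")
        if self.n_endothelial_cells < 1:
            raise ValueError("need at least one endothelial cell")
        if not 0.0 <= self.junction_wander_amplitude < 0.5:
            raise ValueError("junction wander amplitude must lie in [0, 0.5)")
        for spec in self.iep_specs:
            if not isinstance(spec, IepSpec):
                raise TypeError("iep_specs entries must be IepSpec")

    # -- derived geometry --------------------------------------------------
    @property
    def spacing_nm(self) -> tuple[float, float, float]:
        return (self.slice_thickness_nm, self.pixel_size_nm, self.pixel_size_nm)

    def outer_radius_nm(self) -> np.ndarray:
        """Per-slice outer endothelial radius (nm)."""
        anchors = sorted(self.capillary_radius_profile)
        zs = np.array([a[0] for a in anchors], dtype=float)
        rs = np.array([a[1] * 1000.0 for a in anchors], dtype=float)
        return np.interp(np.arange(self.n_slices, dtype=float), zs, rs)

    def cells_per_slice(self) -> np.ndarray:
        """Per-slice endothelial cell (sector) count."""
        n = np.full(self.n_slices, self.n_endothelial_cells, dtype=int)
        if self.cell_count_schedule:
            for z0, count in sorted(self.cell_count_schedule):
                if count < 1:
                    raise ValueError("cell counts must be >= 1")
                n[max(z0, 0):] = count
        return n

    def villus_radius_nm(self) -> float:
        if self.villus_radius_um is not None:
            return self.villus_radius_um * 1000.0
        h, w = self.image_shape
        return 0.48 * min(h, w) * self.pixel_size_nm


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom, reporting realised quantities."""

    true_pericyte_fraction: float
    iep_records: list[IEPRecord]
    cells_per_slice: list[int]
    true_diameter_per_slice: list[float]
    total_tissue_volume_nm3: float
    pericyte_fraction_unreachable: bool = False

    def to_dict(self) -> dict:
        return {
            "true_pericyte_fraction": self.true_pericyte_fraction,
            "iep_records": [
                {
                    "iep_id": r.iep_id,
                    "base": list(r.base),
                    "tip": list(r.tip),
                    "width_nm": r.width_nm,
                    "donor_cell": r.donor_cell,
                    "acceptor_cell": r.acceptor_cell,
                    "branched": r.branched,
                    "length_nm": r.length_nm,
                    "cls": r.cls.value if r.cls is not None else None,
                }
                for r in self.iep_records
            ],
            "cells_per_slice": self.cells_per_slice,
            "true_diameter_per_slice": self.true_diameter_per_slice,
            "total_tissue_volume_nm3": self.total_tissue_volume_nm3,
            "pericyte_fraction_unreachable": self.pericyte_fraction_unreachable,
        }


# ---------------------------------------------------------------------------
# sector geometry
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    """A z-range with a fixed number of angular cell sectors."""

    z0: int
    z1: int  # exclusive
    n: int
    cell_labels: np.ndarray  # label per sector
    phi0: float
    psi: np.ndarray  # per-boundary wander phases

    def boundaries(self, z: int, cfg: PhantomConfig) -> np.ndarray:
        """Sector boundary angles at slice z (unsorted, j = 0..n-1)."""
        width = 2.0 * math.pi / self.n
        period_nm = cfg.junction_wander_period_um * 1000.0
        phase = 2.0 * math.pi * z * cfg.slice_thickness_nm / period_nm
        wander = cfg.junction_wander_amplitude * width * np.sin(phase + self.psi)
        return self.phi0 + width * np.arange(self.n) + wander


def _build_segments(cfg: PhantomConfig, rng: np.random.Generator) -> list[_Segment]:
    counts = cfg.cells_per_slice()
    change = np.flatnonzero(np.diff(counts)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [cfg.n_slices]])
    segments = []
    next_label = FIRST_CELL_LABEL
    for z0, z1 in zip(starts, ends):
        n = int(counts[z0])
        labels = np.arange(next_label, next_label + n)
        next_label += n
        segments.append(
            _Segment(
                z0=int(z0),
                z1=int(z1),
                n=n,
                cell_labels=labels,
                phi0=float(rng.uniform(0.0, 2.0 * math.pi)),
                psi=rng.uniform(0.0, 2.0 * math.pi, size=n),
            )
        )
    return segments


def _sector_index(theta: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Sector index for each angle, given that slice's boundary angles."""
    b0 = boundaries[0]
    rel_b = np.mod(boundaries - b0, 2.0 * math.pi)
    rel_b[0] = 0.0
    rel = np.mod(theta - b0, 2.0 * math.pi)
    return np.searchsorted(rel_b, rel, side="right") - 1


# ---------------------------------------------------------------------------
# abluminal face enumeration (shared by generator and oracle)
# ---------------------------------------------------------------------------

def _face_slabs(axis: int, sign: int):
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if sign > 0:
        src[axis] = slice(0, -1)
        dst[axis] = slice(1, None)
    else:
        src[axis] = slice(1, None)
        dst[axis] = slice(0, -1)
    return tuple(src), tuple(dst)


def _iter_faces(wall: np.ndarray, abluminal: np.ndarray):
    """Yield, per direction, (face mask in slab frame, neighbour offset, slabs)."""
    for axis in range(3):
        for sign in (1, -1):
            src, dst = _face_slabs(axis, sign)
            faces = wall[src] & abluminal[dst]
            yield axis, sign, faces, src, dst


def true_surface_coverage(stack: LabelStack) -> float:
    """Exhaustively enumerated pericyte coverage of the abluminal surface.

    Counts every voxel face between wall tissue (endothelium or IEP) and a
    non-wall, non-lumen voxel, and returns the fraction of those faces whose
    abluminal neighbour is pericyte.  Faces on the stack boundary (no
    neighbour voxel) are surface truncated by the field of view and are not
    counted.  This is the brute-force oracle the grid estimator is validated
    against.
    """
    wall = stack.mask(*WALL_KINDS)
    if not wall.any():
        raise EmptyVesselError("stack contains no endothelial voxels")
    lumen = stack.mask("lumen")
    peri = stack.mask("pericyte")
    abluminal = ~wall & ~lumen
    total = 0
    covered = 0
    for _, _, faces, _, dst in _iter_faces(wall, abluminal):
        total += int(faces.sum())
        if peri.any():
            covered += int((faces & peri[dst]).sum())
    if total == 0:
        raise EmptyVesselError("endothelium has no abluminal surface")
    return covered / total


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_phantom(
    config: PhantomConfig, vessel_id: int = 1
) -> tuple[LabelStack, PhantomTruth]:
    """Generate a seeded single-vessel label stack and its ground truth.

    Deterministic for a fixed configuration: the root seed is split into
    independent sub-streams (junction layout, pericyte placement) so that
    changing one feature leaves the others untouched.
    """
    cfg = config
    Z = cfg.n_slices
    H, W = cfg.image_shape
    dz, dy, dx = cfg.spacing_nm
    root = np.random.SeedSequence(cfg.rng_seed)
    junction_ss, pericyte_ss = root.spawn(2)
    rng_j = np.random.default_rng(junction_ss)
    rng_p = np.random.default_rng(pericyte_ss)

    r_out = cfg.outer_radius_nm()
    wall_nm = cfg.wall_thickness_um * 1000.0
    r_lum = r_out - wall_nm
    if np.any(r_lum <= 0):
        raise PhantomSpecError("wall thickness exceeds the capillary radius")
    villus_r = cfg.villus_radius_nm()
    stb_nm = cfg.stb_thickness_um * 1000.0
    peri_nm = cfg.pericyte_thickness_um * 1000.0
    clearance = villus_r - stb_nm - (r_out.max() + peri_nm)
    if clearance <= 2 * cfg.pixel_size_nm:
        raise PhantomSpecError(
            "villus radius leaves no stroma outside the vessel; enlarge the "
            "field or shrink the vessel"
        )

    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    ry = (yy - cy) * dy
    rx = (xx - cx) * dx
    r = np.hypot(ry, rx)
    theta = np.mod(np.arctan2(ry, rx), 2.0 * math.pi)

    segments = _build_segments(cfg, rng_j)
    seg_of = np.empty(Z, dtype=int)
    for i, seg in enumerate(segments):
        seg_of[seg.z0:seg.z1] = i

    voxels = np.empty((Z, H, W), dtype=np.uint16)
    for z in range(Z):
        lab = np.full((H, W), L_IVS, dtype=np.uint16)
        lab[r < villus_r] = L_STB
        lab[r < villus_r - stb_nm] = L_STROMA
        ring = (r >= r_lum[z]) & (r < r_out[z])
        if ring.any():
            seg = segments[seg_of[z]]
            idx = _sector_index(theta[ring], seg.boundaries(z, cfg))
            lab[ring] = seg.cell_labels[idx]
        lab[r < r_lum[z]] = L_LUMEN
        voxels[z] = lab

    semantics: dict[int, Role] = {
        L_IVS: Role("intervillous_space"),
        L_STB: Role("syncytiotrophoblast"),
        L_STROMA: Role("stroma"),
        L_LUMEN: Role("lumen", vessel=vessel_id),
        L_PERICYTE: Role("pericyte", vessel=vessel_id),
    }
    cell_id = 0
    for seg in segments:
        for lab in seg.cell_labels:
            cell_id += 1
            semantics[int(lab)] = Role("endothelial_cell", vessel=vessel_id, cell=cell_id)

    iep_records = _carve_ieps(voxels, cfg, segments, seg_of, r_out, r_lum,
                              (cy, cx), semantics, vessel_id)

    unreachable = False
    if cfg.pericyte_target_fraction > 0:
        unreachable = _place_pericytes(
            voxels, cfg, rng_p, r, theta, r_out, peri_nm
        )

    stack = LabelStack(voxels=voxels, spacing_nm=cfg.spacing_nm, semantics=semantics)
    stack.validate()

    fraction = true_surface_coverage(stack)
    truth = PhantomTruth(
        true_pericyte_fraction=fraction,
        iep_records=iep_records,
        cells_per_slice=[int(c) for c in cfg.cells_per_slice()],
        true_diameter_per_slice=[2.0 * float(x) / 1000.0 for x in r_out],
        total_tissue_volume_nm3=float(np.count_nonzero(voxels != L_IVS)) * dz * dy * dx,
        pericyte_fraction_unreachable=unreachable,
    )
    return stack, truth


def _place_pericytes(voxels, cfg, rng, r, theta, r_out, peri_nm) -> bool:
    """Paint helical longitudinal pericyte processes on the abluminal shell.

    Each of ``n_pericyte_processes`` processes follows an angular path
    ``alpha_p(z) = alpha_p0 + twist * z / (Z-1)`` with starting angles
    stratified (with jitter) around the circumference.  A face or shell
    voxel belongs to a process if its arc distance to the path is at most a
    global half-width ``t``.  ``t`` is chosen as the quantile of the per-face
    arc distances at the target fraction, so the realised covered fraction
    of abluminal faces matches the target to within the face-count
    granularity.  Returns True when the target was unreachable (flagged,
    realised fraction reported in the truth).
    """
    Z = cfg.n_slices
    dz = cfg.slice_thickness_nm
    k = cfg.n_pericyte_processes
    twist = cfg.pericyte_twist_rad
    base_phase = rng.uniform(0.0, 2.0 * math.pi)
    jitter = rng.uniform(-0.3, 0.3, size=k)
    alpha0 = base_phase + 2.0 * math.pi * (np.arange(k) + 0.5 + jitter) / k
    r_mean = float(r_out.mean())

    def _arc_dist(th, z):
        """Min arc distance (nm) from (theta, z) points to any process path."""
        a = alpha0[None, :] + twist * (np.asarray(z, dtype=float)[:, None] / max(Z - 1, 1))
        d = np.abs(np.mod(th[:, None] - a + math.pi, 2.0 * math.pi) - math.pi)
        return r_mean * d.min(axis=1)

    # enumerate abluminal faces and the (z, theta) of their shell neighbours;
    # every label >= FIRST_CELL_LABEL is wall tissue (cells and IEPs)
    wall = voxels >= FIRST_CELL_LABEL
    lumen = voxels == L_LUMEN
    abluminal = ~wall & ~lumen
    face_m = []
    for axis, sign, faces, src, dst in _iter_faces(wall, abluminal):
        nz, ny, nx = np.nonzero(faces)
        if nz.size == 0:
            continue
        coords = [nz, ny, nx]
        if sign > 0:
            coords[axis] = coords[axis] + 1
        nz, ny, nx = coords
        coverable = (
            (voxels[nz, ny, nx] == L_STROMA)
            & (r[ny, nx] >= r_out[nz])
            & (r[ny, nx] < r_out[nz] + peri_nm)
        )
        m = np.where(coverable, _arc_dist(theta[ny, nx], nz), np.inf)
        face_m.append(m)
    face_m = np.concatenate(face_m)
    if face_m.size == 0:
        return True

    target = cfg.pericyte_target_fraction
    finite = np.isfinite(face_m)
    max_reachable = finite.mean()
    if target >= max_reachable:
        t_star = np.inf  # cover everything coverable
    else:
        t_star = float(np.quantile(face_m[finite], target / max_reachable))
    realised = float((face_m <= t_star).mean())
    unreachable = abs(realised - target) > 0.01

    for z in range(Z):
        shell = (
            (voxels[z] == L_STROMA)
            & (r >= r_out[z])
            & (r < r_out[z] + peri_nm)
        )
        if not shell.any():
            continue
        sy, sx = np.nonzero(shell)
        member = _arc_dist(theta[sy, sx], np.full(sy.size, z)) <= t_star
        voxels[z, sy[member], sx[member]] = L_PERICYTE
    return unreachable


def _carve_ieps(voxels, cfg, segments, seg_of, r_out, r_lum, centre,
                semantics, vessel_id) -> list[IEPRecord]:
    """Carve each requested protrusion as a capsule rooted on a junction."""
    Z = cfg.n_slices
    dz, dy, dx = cfg.spacing_nm
    cy, cx = centre
    spacing = np.array([dz, dy, dx])
    vox_diag = float(np.linalg.norm(spacing))
    records: list[IEPRecord] = []
    endo_labels = np.concatenate([s.cell_labels for s in segments])

    for i, spec in enumerate(cfg.iep_specs):
        label = FIRST_IEP_LABEL + i
        iep_id = i + 1
        L = spec.length_um * 1000.0
        Wd = spec.width_um * 1000.0
        z0 = int(round(spec.junction_pos * (Z - 1)))
        seg = segments[seg_of[z0]]
        j = spec.donor_cell % seg.n
        j_acc = (j + 1) % seg.n
        theta_b = float(seg.boundaries(z0, cfg)[j_acc])
        donor_label = int(seg.cell_labels[j])
        acceptor_label = int(seg.cell_labels[j_acc])

        alpha = cfg.iep_tilt
        scale = math.sqrt(1.0 + alpha * alpha)
        L_ax = L / scale
        if z0 * dz + L_ax <= (Z - 1) * dz:
            dirz = 1.0
        elif z0 * dz - L_ax >= 0.0:
            dirz = -1.0
        else:
            raise PhantomSpecError(
                f"iep_specs[{i}]: requested length {spec.length_um} um exceeds the "
                "axial extent available from its junction position"
            )
        # unit axis in physical (z, y, x); tangential tilt points into the
        # acceptor cell (increasing angle)
        u = np.array(
            [dirz, alpha * math.cos(theta_b), -alpha * math.sin(theta_b)]
        ) / scale

        # base sits mid-wall on the junction line, nudged into the acceptor
        # and pre-compensated for the radial drift of the straight axis
        r_mid = (r_lum[z0] + r_out[z0]) / 2.0
        drift = (alpha * L / scale) ** 2 / (2.0 * r_mid)
        r_base = r_mid - drift / 2.0
        offset = Wd / 2.0
        base = np.array(
            [
                z0 * dz,
                cy * dy + r_base * math.sin(theta_b) + offset * math.cos(theta_b),
                cx * dx + r_base * math.cos(theta_b) - offset * math.sin(theta_b),
            ]
        )
        tip = base + L * u

        carved = _carve_capsule(voxels, base, tip, Wd / 2.0, spacing, endo_labels, label)
        if spec.branched:
            mid = base + 0.45 * L * u
            u2 = np.array(
                [dirz, -alpha * math.cos(theta_b), alpha * math.sin(theta_b)]
            ) / scale
            _carve_capsule(
                voxels, mid, mid + 0.3 * L * u2, 0.3 * Wd, spacing, endo_labels, label
            )
            carved = np.argwhere(voxels == label)
        if carved.size == 0:
            raise PhantomSpecError(f"iep_specs[{i}]: capsule fell outside the wall")
        phys = carved * spacing
        base_vox = carved[np.argmin(((phys - base) ** 2).sum(axis=1))]
        tip_vox = carved[np.argmin(((phys - tip) ** 2).sum(axis=1))]
        if np.linalg.norm(tip_vox * spacing - tip) > vox_diag:
            raise PhantomSpecError(
                f"iep_specs[{i}]: protrusion does not fit inside the acceptor "
                "cell's extent"
            )
        semantics[label] = Role("iep", vessel=vessel_id, iep=iep_id)
        length = chord_length(base_vox, tip_vox, spacing)
        records.append(
            IEPRecord(
                iep_id=iep_id,
                base=tuple(int(c) for c in base_vox),
                tip=tuple(int(c) for c in tip_vox),
                width_nm=Wd,
                donor_cell=semantics[donor_label].cell,
                acceptor_cell=semantics[acceptor_label].cell,
                branched=spec.branched,
                length_nm=length,
                cls=classify_protrusion(length, Wd),
            )
        )
    return records


def _carve_capsule(voxels, a, b, radius, spacing, endo_labels, label) -> np.ndarray:
    """Label all wall voxels within ``radius`` of segment a-b; return coords."""
    Z, H, W = voxels.shape
    lo = np.minimum(a, b) - radius - 2 * spacing
    hi = np.maximum(a, b) + radius + 2 * spacing
    z0, y0, x0 = [max(int(np.floor(l / s)), 0) for l, s in zip(lo, spacing)]
    z1 = min(int(np.ceil(hi[0] / spacing[0])) + 1, Z)
    y1 = min(int(np.ceil(hi[1] / spacing[1])) + 1, H)
    x1 = min(int(np.ceil(hi[2] / spacing[2])) + 1, W)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return np.empty((0, 3), dtype=int)
    gz, gy, gx = np.mgrid[z0:z1, y0:y1, x0:x1]
    pts = np.stack([gz, gy, gx], axis=-1) * spacing
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
    closest = a + t[..., None] * ab if denom > 0 else np.broadcast_to(a, pts.shape)
    dist2 = ((pts - closest) ** 2).sum(axis=-1)
    inside = dist2 <= radius * radius
    sub = voxels[z0:z1, y0:y1, x0:x1]
    mask = inside & np.isin(sub, endo_labels)
    sub[mask] = label
    coords = np.argwhere(voxels == label)
    return coords


# ---------------------------------------------------------------------------
# study phantoms
# ---------------------------------------------------------------------------

def arteriole_venule_phantoms(
    rng_seed: int = 0,
    n_slices: int = 540,
    slice_thickness_nm: float = 100.0,
    pixel_size_nm: float = 50.0,
    block: int = 25,
) -> dict[str, tuple[LabelStack, PhantomTruth]]:
    """Paired intermediate-villus vessel phantoms for series summaries.

    Builds a venule (the larger, lower-resistance vessel; mean diameter
    22.0 um, ring cell counts averaging 10) and an arteriole (11.7 um,
    averaging 7.5), each spanning ``n_slices`` at intermediate-villus
    magnification.  Diameters and cell counts alternate in ``block``-slice
    blocks around their means, so sampling every ``block`` slices recovers
    the construction means exactly and gives both series realistic spread.
    """
    root = np.random.SeedSequence(rng_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2)]

    def _anchors(r0, amp):
        return tuple(
            (k * block, r0 + (amp if k % 2 == 0 else -amp))
            for k in range(n_slices // block + 1)
        )

    def _schedule(lo, hi):
        return tuple(
            (k * block, hi if k % 2 == 0 else lo)
            for k in range(n_slices // block + 1)
        )

    venule_cfg = PhantomConfig(
        n_slices=n_slices,
        image_shape=(520, 520),
        pixel_size_nm=pixel_size_nm,
        slice_thickness_nm=slice_thickness_nm,
        capillary_radius_profile=_anchors(11.0, 0.65),
        wall_thickness_um=1.2,
        pericyte_target_fraction=0.0,
        villus_radius_um=12.5,
        stb_thickness_um=0.4,
        cell_count_schedule=_schedule(9, 11),
        rng_seed=seeds[0],
    )
    arteriole_cfg = PhantomConfig(
        n_slices=n_slices,
        image_shape=(320, 320),
        pixel_size_nm=pixel_size_nm,
        slice_thickness_nm=slice_thickness_nm,
        capillary_radius_profile=_anchors(5.85, 0.9),
        wall_thickness_um=1.2,
        pericyte_target_fraction=0.0,
        villus_radius_um=7.6,
        stb_thickness_um=0.4,
        cell_count_schedule=_schedule(7, 8),
        rng_seed=seeds[1],
    )
    return {
        "venule": generate_phantom(venule_cfg, vessel_id=1),
        "arteriole": generate_phantom(arteriole_cfg, vessel_id=2),
    }


def junction_diameter_phantom(
    rng_seed: int = 0,
    n_slices: int = 300,
    block: int = 25,
) -> tuple[LabelStack, PhantomTruth]:
    """Capillary phantom whose ring cell count grows with its calibre.

    Radius anchors every ``block`` slices are drawn uniformly from the
    capillary range and the sector count is tied monotonically to the local
    radius, mimicking the observation that wider profiles are lined by more
    endothelial cells.  Sampling every ``block``-th slice therefore yields
    junction-count/diameter pairs (with ties) of positive rank correlation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    n_anchor = n_slices // block + 1
    radii = rng.uniform(1.2, 2.6, size=n_anchor)
    cells = 3 + np.minimum(((radii - 1.2) / 1.4 * 5).astype(int), 4)
    cfg = PhantomConfig(
        n_slices=n_slices,
        capillary_radius_profile=tuple(
            (k * block, float(r)) for k, r in enumerate(radii)
        ),
        wall_thickness_um=0.6,
        pericyte_target_fraction=0.0,
        cell_count_schedule=tuple((k * block, int(c)) for k, c in enumerate(cells)),
        rng_seed=int(rng.integers(2**31)),
    )
    return generate_phantom(cfg)
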