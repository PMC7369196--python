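"""Protrusion measurement, classification and density arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import villistereo as vs
from villistereo.morphometry import (
    IepTooShortError,
    ProtrusionClass,
    flag_stack_jumps,
    format_density_millions,
    validate_iep_connectivity,
)

SPACING = (50.0, 25.0, 25.0)


# -- chord length -----------------------------------------------------------

@pytest.mark.parametrize(
    "base, tip, spacing, expected",
    [
        ((5, 6, 7), (5, 6, 7), SPACING, 0.0),
        ((0, 0, 0), (31, 0, 0), SPACING, 1550.0),  # 31 slice intervals of 50 nm
        ((3, 4, 0), (0, 0, 0), (1, 1, 1), 5.0),
    ],
)
def test_chord_length_examples(base, tip, spacing, expected):
    assert vs.chord_length(base, tip, spacing) == pytest.approx(expected)


coords = st.tuples(*[st.integers(0, 50)] * 3)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(a=coords, b=coords, c=coords)
def test_chord_length_is_a_metric(a, b, c):
    d_ab = vs.chord_length(a, b, SPACING)
    assert d_ab == vs.chord_length(b, a, SPACING)
    assert (d_ab == 0) == (a == b)
    assert d_ab <= vs.chord_length(a, c, SPACING) + vs.chord_length(c, b, SPACING) + 1e-9


# -- classification ---------------------------------------------------------

@pytest.mark.parametrize(
    "length, width, expected",
    [
        (1740.0, 230.0, ProtrusionClass.IEP),  # ratio ~7.6
        (470.0, 200.0, ProtrusionClass.COMPLEX_JUNCTION),  # ratio ~2.35
        (400.0, 100.0, ProtrusionClass.IEP),  # ratio exactly 4, boundary inclusive
        (390.0, 100.0, ProtrusionClass.COMPLEX_JUNCTION),
    ],
)
def test_classify_protrusion(length, width, expected):
    assert vs.classify_protrusion(length, width) is expected


def test_classify_rejects_nonpositive():
    with pytest.raises(ValueError):
        vs.classify_protrusion(0.0, 100.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    length=st.floats(1.0, 1e4), width=st.floats(1.0, 1e4),
    thr=st.floats(1.0, 20.0),
)
def test_classification_partitions(length, width, thr):
    cls = vs.classify_protrusion(length, width, thr)
    assert cls in (ProtrusionClass.IEP, ProtrusionClass.COMPLEX_JUNCTION)
    assert (cls is ProtrusionClass.IEP) == (length / width >= thr)


# -- density ----------------------------------------------------------------

def test_density_worked_arithmetic():
    raw = vs.iep_density_raw(89, 6.41e14)
    assert raw == pytest.approx(1.3885e8, rel=1e-3)
    assert round(raw / 1e6) == 139
    adj = vs.adjust_density(raw, 0.35, 0.39)
    assert adj == pytest.approx(3.52e7, rel=1e-2)
    assert round(adj / 1e6) == 35
    assert format_density_millions(raw) == "139 million per cm^3"
    assert format_density_millions(adj) == "35 million per cm^3"


@pytest.mark.parametrize(
    "n, volume, expected",
    [(0, 1e14, 0.0), (1, 1e21, 1.0)],
)
def test_density_raw_units(n, volume, expected):
    assert vs.iep_density_raw(n, volume) == pytest.approx(expected)


def test_density_requires_positive_volume():
    with pytest.raises(ValueError):
        vs.iep_density_raw(5, 0.0)


def test_adjust_density_limits_and_monotonicity():
    assert vs.adjust_density(7.0, 0.0, 1.0) == 7.0
    assert vs.adjust_density(7.0, 1.0, 0.5) == 0.0
    base = vs.adjust_density(1e8, 0.3, 0.4)
    assert vs.adjust_density(1e8, 0.4, 0.4) < base  # more IVS -> lower
    assert vs.adjust_density(1e8, 0.3, 0.5) > base  # more terminal villi -> higher
    with pytest.raises(ValueError):
        vs.adjust_density(1e8, 1.5, 0.4)


def test_density_recovers_phantom_truth(morphometry_phantom):
    """Counting iep labels over the phantom tissue volume is exact."""
    _, stack, truth = morphometry_phantom
    n = len(stack.labels_of("iep"))
    d = vs.iep_density_raw(n, truth.total_tissue_volume_nm3)
    assert d == vs.iep_density_raw(
        len(truth.iep_records), truth.total_tissue_volume_nm3
    )


# -- axial extent -----------------------------------------------------------

@pytest.mark.parametrize(
    "n, dz, expected",
    [(367, 50.0, 18.35), (1, 50.0, 0.05), (540, 100.0, 54.0)],
)
def test_axial_extent(n, dz, expected):
    assert vs.axial_extent(n, dz) == pytest.approx(expected)


# -- width measurement ------------------------------------------------------

def _protrusion_volume(shaft_radius=75.0, bulb_radius=None, length_nm=1200.0):
    """Donor slab + acceptor block + a z-axis protrusion of known shape."""
    dz, dy, dx = SPACING
    Z, H, W = 48, 48, 48
    vox = np.full((Z, H, W), 10, dtype=np.uint16)  # acceptor cell
    vox[:4] = 11  # donor cell slab
    zz, yy, xx = np.mgrid[0:Z, 0:H, 0:W]
    ry, rx = (yy - 24) * dy, (xx - 24) * dx
    rr = np.hypot(ry, rx)
    z_nm = (zz - 4) * dz
    shaft = (rr <= shaft_radius) & (z_nm >= 0) & (z_nm <= length_nm)
    vox[shaft] = 1000
    if bulb_radius is not None:
        dist = np.sqrt(ry**2 + rx**2 + (z_nm - length_nm) ** 2)
        vox[dist <= bulb_radius] = 1000
    sem = {
        10: vs.Role("endothelial_cell", cell=1),
        11: vs.Role("endothelial_cell", cell=2),
        1000: vs.Role("iep", iep=1),
    }
    return vs.LabelStack(voxels=vox, spacing_nm=SPACING, semantics=sem)


def test_width_of_cylindrical_shaft():
    stack = _protrusion_volume(shaft_radius=115.0)
    w = vs.iep_width(stack, 1)
    assert w == pytest.approx(230.0, abs=np.linalg.norm(SPACING))


def test_width_reports_tip_bulb_not_shaft():
    stack = _protrusion_volume(shaft_radius=75.0, bulb_radius=200.0)
    w = vs.iep_width(stack, 1)
    assert w == pytest.approx(400.0, abs=np.linalg.norm(SPACING))


def test_width_single_voxel_is_one_pixel():
    vox = np.full((6, 8, 8), 10, dtype=np.uint16)
    vox[0] = 11
    vox[3, 4, 4] = 1000
    sem = {
        10: vs.Role("endothelial_cell", cell=1),
        11: vs.Role("endothelial_cell", cell=2),
        1000: vs.Role("iep", iep=1),
    }
    stack = vs.LabelStack(voxels=vox, spacing_nm=SPACING, semantics=sem)
    assert vs.iep_width(stack, 1, neck_exclusion_nm=0.0) == pytest.approx(25.0)


def test_width_shorter_than_neck_errors_with_id():
    stack = _protrusion_volume(shaft_radius=60.0, length_nm=60.0)
    with pytest.raises(IepTooShortError, match="iep 1"):
        vs.iep_width(stack, 1, neck_exclusion_nm=500.0)


def test_phantom_widths_recover_specs(morphometry_phantom):
    cfg, stack, truth = morphometry_phantom
    diag = float(np.linalg.norm(stack.spacing_nm))
    for rec, spec in zip(truth.iep_records, cfg.iep_specs):
        w = vs.iep_width(stack, rec.iep_id)
        assert w == pytest.approx(spec.width_um * 1000.0, abs=diag)


def test_phantom_ieps_touch_their_donor(morphometry_phantom):
    _, stack, truth = morphometry_phantom
    for rec in truth.iep_records:
        assert validate_iep_connectivity(stack, rec.iep_id, rec.donor_cell)
        assert not validate_iep_connectivity(stack, rec.iep_id, rec.acceptor_cell + 99)


# -- summaries --------------------------------------------------------------

def _rec(i, length_nm, placenta=None):
    return vs.IEPRecord(
        iep_id=i, base=(0, 0, 0), tip=(0, 0, 1), width_nm=200.0,
        placenta_id=placenta, length_nm=length_nm,
    )


def test_summary_single_value():
    s = vs.summarize_ieps([_rec(1, 1740.0)])
    assert s["overall"]["length_um"] == {
        "median": 1.74, "min": 1.74, "max": 1.74, "n": 1
    }


def test_per_placenta_median_of_medians_differs_from_pooled():
    records = [
        _rec(1, 1000.0, "A"), _rec(2, 3000.0, "A"), _rec(3, 5000.0, "B")
    ]
    s = vs.summarize_ieps(records)
    assert s["overall"]["length_um"]["median"] == pytest.approx(3.0)
    assert s["per_placenta"]["length_um"]["median"] == pytest.approx(3.5)
    assert s["per_placenta"]["n_placentas"] == 2


def test_pooled_range_is_min_max_of_draw():
    rng = np.random.default_rng(1)
    lengths = rng.uniform(400.0, 7100.0, size=88)
    s = vs.summarize_ieps([_rec(i, l) for i, l in enumerate(lengths)])
    assert s["overall"]["length_um"]["min"] == pytest.approx(lengths.min() / 1000)
    assert s["overall"]["length_um"]["max"] == pytest.approx(lengths.max() / 1000)


def test_summary_rejects_empty():
    with pytest.raises(ValueError):
        vs.summarize_ieps([])


def test_stack_jump_flagging():
    records = [
        vs.IEPRecord(iep_id=1, base=(2, 0, 0), tip=(8, 0, 0), width_nm=100.0),
        vs.IEPRecord(iep_id=2, base=(10, 0, 0), tip=(12, 0, 0), width_nm=100.0),
    ]
    assert flag_stack_jumps(records, missing_slices=[5]) == [1]
    assert flag_stack_jumps(records, missing_slices=[9]) == []
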