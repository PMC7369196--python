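"""Shared phantom fixtures.

The heavier study phantoms are generated once per session; their seeds are
fixed so every run exercises identical geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

import villistereo as vs
from villistereo.phantom import junction_diameter_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Fast sub-micron capillary phantom for unit tests."""
    cfg = vs.PhantomConfig(
        n_slices=60,
        image_shape=(96, 96),
        capillary_radius_profile=((0, 0.8),),
        wall_thickness_um=0.3,
        pericyte_target_fraction=0.3,
        pericyte_thickness_um=0.15,
        villus_radius_um=1.12,
        stb_thickness_um=0.1,
        rng_seed=0,
    )
    return cfg, *vs.generate_phantom(cfg)


@pytest.fixture(scope="session")
def default_phantom():
    """The default terminal-villus capillary stack with 15% pericyte cover."""
    cfg = vs.PhantomConfig(rng_seed=11)
    return cfg, *vs.generate_phantom(cfg)


@pytest.fixture(scope="session")
def morphometry_phantom():
    """Capillary carrying protrusions at the observed per-placenta sizes."""
    specs = (
        vs.IepSpec(0.2, 0.15, donor_cell=0, junction_pos=0.25),
        vs.IepSpec(1.74, 0.23, donor_cell=1, junction_pos=0.5),
        vs.IepSpec(5.2, 0.50, donor_cell=2, junction_pos=0.3),
    )
    cfg = vs.PhantomConfig(
        pericyte_target_fraction=0.0, iep_specs=specs, rng_seed=7
    )
    return cfg, *vs.generate_phantom(cfg)


@pytest.fixture(scope="session")
def vessel_pair():
    """Paired arteriole/venule phantoms built to the study means."""
    return vs.arteriole_venule_phantoms(rng_seed=2)


@pytest.fixture(scope="session")
def jd_phantom():
    """Capillary whose ring cell count grows with its calibre."""
    return junction_diameter_phantom(rng_seed=3)
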