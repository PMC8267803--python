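"""Shared fixtures: small deterministic geometries and solved unit loads."""

from __future__ import annotations

import numpy as np
import pytest

from boneload.images import BinaryMask, DensityImage, binarise
from boneload.insilico import AdvectionConfig, generate_phantom
from boneload.microfe import DIRECTIONS, build_mesh, solve_unit_loads


@pytest.fixture(scope="session")
def phantom():
    """A 24^3 trabecular phantom at HR-pQCT-like spacing."""
    return generate_phantom((24, 24, 24), seed=3)


@pytest.fixture(scope="session")
def phantom_mask(phantom):
    return binarise(phantom, 320.0)


@pytest.fixture(scope="session")
def unit_loads(phantom_mask):
    """Six unit-load SED fields on the phantom (uniform tissue modulus)."""
    mesh = build_mesh(phantom_mask, tissue_modulus=6800.0, poisson=0.3)
    return solve_unit_loads(mesh, DIRECTIONS, platen_layers=1)


@pytest.fixture()
def porous_mask():
    """A small connected porous block (fast FE)."""
    rng = np.random.default_rng(42)
    from scipy import ndimage as ndi

    f = ndi.gaussian_filter(rng.standard_normal((12, 12, 12)), 1.5)
    m = f > np.quantile(f, 0.70)
    m[:, :, 0] = True
    m[:, :, -1] = True
    lbl, _ = ndi.label(m, structure=np.ones((3, 3, 3), bool))
    m &= lbl == lbl[0, 0, 0]
    return BinaryMask(m, 0.05)


@pytest.fixture()
def advection_config():
    return AdvectionConfig()


def random_density(shape, seed, spacing=0.03, lo=0.0, hi=800.0):
    rng = np.random.default_rng(seed)
    return DensityImage(rng.uniform(lo, hi, size=shape), spacing)
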