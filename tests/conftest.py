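import numpy as np
import pytest

from latwin.myocyte import ConductanceScaling
from latwin.substrate import (SheetMesh, SubstrateMap, assign_conductivity,
                              build_fiber_field, segment_regions)


def make_uniform_substrate(nx=40, ny=12, spacing_mm=0.25, fibrotic=False,
                           fiber_angle_deg=0.0, lesion_mask=None):
    """Homogeneous sheet substrate (no stochastic fibrosis draw)."""
    mesh = SheetMesh(nx, ny, spacing_mm)
    n = mesh.n_nodes
    fib = np.full(n, bool(fibrotic))
    lesion = (np.zeros(n, dtype=bool) if lesion_mask is None
              else np.asarray(lesion_mask, dtype=bool))
    fib[lesion] = False
    sigma_l, sigma_t = assign_conductivity(fib)
    return SubstrateMap(
        mesh=mesh,
        voltage_mV=np.full(n, 5.0),
        covered=np.ones(n, dtype=bool),
        fibrotic=fib,
        fiber=build_fiber_field(mesh, "uniform",
                                {"angle_deg": fiber_angle_deg}),
        sigma_l=sigma_l, sigma_t=sigma_t,
        region=segment_regions(mesh, lesion),
        lesion=lesion,
    )


@pytest.fixture(scope="session")
def unit_scaling():
    return ConductanceScaling.unit()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
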