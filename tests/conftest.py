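"""Shared fixtures: small sampled systems reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from polysia.fragments import build_fragment
from polysia.leus import LEGridSpec, le_build, us_sample
from polysia.potentials import build_model_potential


@pytest.fixture(scope="session")
def double_well():
    """The 25 kJ/mol double-well torsion preset at 300 K."""
    return build_model_potential("double_well_1d")


@pytest.fixture(scope="session")
def leus_1d(double_well):
    """A complete 1D LEUS run (build -> freeze -> umbrella sample)."""
    grid = LEGridSpec(("phi",))
    bias = le_build(double_well, grid, 500_000, seed=21)
    bias.freeze()
    traj = us_sample(double_well, bias, 1_000_000, save_stride=1, seed=22)
    return {"potential": double_well, "grid": grid, "bias": bias,
            "trajectory": traj}


@pytest.fixture(scope="session")
def dimer_frame():
    """A single-frame dimer built in state A-like geometry."""
    return build_fragment("dimer", [(60.0, 120.0)],
                          side_torsions={"omega8": -60.0})


@pytest.fixture(scope="session")
def tetramer_frame():
    return build_fragment("tetramer", [(-60.0, -120.0)] * 3, anomer="beta",
                          side_torsions={"omega8": -60.0})


def exact_bin_free_energy(potential, names, grid, temperature):
    """Oracle: exact per-bin free energies from 1-degree quadrature,
    aggregated into the LE grid's bins and shifted to zero minimum."""
    from polysia.units import KB

    axis, e = potential.grid_energy(names, 1.0)
    kbt = KB * temperature
    p = np.exp(-(e - e.min()) / kbt)
    p /= p.sum()
    per_bin = 360 // grid.ng
    if p.ndim == 1:
        pb = p.reshape(grid.ng, per_bin).sum(axis=1)
    else:
        pb = p.reshape(grid.ng, per_bin, grid.ng, per_bin).sum(axis=(1, 3))
    g = -kbt * np.log(pb)
    return g - g.min()
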