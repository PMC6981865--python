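"""LEUS engine: deposition accounting, frozen-bias sampling, exact
reweighting and free-energy map construction."""

import numpy as np
import pytest

from polysia.leus import (LEBiasPotential, LEGridSpec, free_energy_map,
                          le_build, reweight_observable, reweight_weights,
                          us_sample)
from polysia.potentials import build_model_potential
from polysia.sampling import metropolis_sample
from polysia.trajectory import TorsionTrajectory
from polysia.units import KB

from conftest import exact_bin_free_energy


def test_zero_steps_leaves_all_weights_zero(double_well):
    bias = le_build(double_well, LEGridSpec(("phi",)), 0)
    assert np.all(bias.weights == 0.0)
    assert bias.n_depositions == 0


def test_pinned_sampler_deposits_k_times_c_at_one_bin():
    """With vanishing step size the chain never leaves its bin, so after
    k depositions the bias at that bin center equals k*c."""
    pot = build_model_potential("flat")
    grid = LEGridSpec(("phi",), c=0.005)
    k = 137
    bias = le_build(pot, grid, k, deposition_stride=1, seed=0,
                    step_size=1e-9, start=[-175.0])  # center of bin 0
    assert bias.n_depositions == k
    assert bias.weights[0] == pytest.approx(k * grid.c)
    assert np.all(bias.weights[1:] == 0.0)
    assert bias.energy([-175.0]) == pytest.approx(k * grid.c, rel=1e-6)
    assert bias.total_deposited() == pytest.approx(k * grid.c)


def test_build_flattens_sampling_coverage(double_well):
    """After a 1e6-step build the biased sampler covers nearly all bins
    of the 25 kJ/mol double well while the unbiased one stays trapped
    near the wells (frames saved at the sparse trajectory stride)."""
    grid = LEGridSpec(("phi",))
    bias = le_build(double_well, grid, 1_000_000, seed=31)
    bias.freeze()
    stride = 100
    unbiased = metropolis_sample(double_well, 1_000_000, seed=32,
                                 save_stride=stride)
    biased = us_sample(double_well, bias, 1_000_000, save_stride=stride,
                       seed=32)
    cover_unbiased = len(set(grid.bin_index(unbiased.frames)[0])) / grid.ng
    cover_biased = len(set(grid.bin_index(biased.frames)[0])) / grid.ng
    assert cover_biased >= 0.95
    assert cover_unbiased < 0.70
    assert cover_biased >= cover_unbiased


def test_us_sample_requires_frozen_bias(double_well):
    bias = le_build(double_well, LEGridSpec(("phi",)), 1_000, seed=1)
    with pytest.raises(ValueError, match="frozen"):
        us_sample(double_well, bias, 1_000)


def test_frozen_bias_weights_immutable(double_well):
    bias = le_build(double_well, LEGridSpec(("phi",)), 1_000, seed=1)
    bias.freeze()
    with pytest.raises(ValueError):
        bias.weights[0] = 99.0


def test_zero_bias_us_matches_plain_metropolis(double_well):
    zero = LEBiasPotential(LEGridSpec(("phi",))).freeze()
    us = us_sample(double_well, zero, 10_000, seed=17)
    plain = metropolis_sample(double_well, 10_000, seed=17)
    assert np.array_equal(us.frames, plain.frames)
    assert np.all(us.bias_energy == 0.0)


def test_recorded_bias_energy_matches_independent_reevaluation(leus_1d):
    traj = leus_1d["trajectory"]
    bias = leus_1d["bias"]
    recomputed = bias.energy(traj.frames)
    assert np.allclose(traj.bias_energy, recomputed, atol=1e-9)


def test_two_2d_biases_apply_jointly():
    """Sampling under both 2D grids records the sum of both biases."""
    pot = build_model_potential("dimer1_like")
    g1 = LEGridSpec(("phi", "psi"))
    g2 = LEGridSpec(("omega8", "omega7"))
    b1 = le_build(pot, g1, 50_000, seed=41).freeze()
    b2 = le_build(pot, g2, 50_000, seed=42).freeze()
    traj = us_sample(pot, [b1, b2], 20_000, save_stride=10, seed=43)
    names = list(traj.torsion_names)
    a1 = traj.frames[:, [names.index("phi"), names.index("psi")]]
    a2 = traj.frames[:, [names.index("omega8"), names.index("omega7")]]
    total = b1.energy(a1) + b2.energy(a2)
    assert np.allclose(traj.bias_energy, total, atol=1e-9)


def test_bias_json_round_trip(leus_1d, tmp_path):
    bias = leus_1d["bias"]
    path = tmp_path / "bias.json"
    bias.to_json(path)
    back = LEBiasPotential.from_json(path)
    assert back.frozen
    assert back.grid == bias.grid
    assert np.allclose(back.weights, bias.weights)
    x = np.linspace(-180, 179, 37)[:, None]
    assert np.allclose(back.energy(x), bias.energy(x))


# ---------------------------------------------------------------------------
# Reweighting
# ---------------------------------------------------------------------------

def test_reweighting_with_zero_bias_equals_plain_mean(double_well):
    traj = metropolis_sample(double_well, 50_000, seed=3)
    obs = np.cos(np.radians(traj.frames[:, 0]))
    mean, err = reweight_observable(traj, obs, 300.0)
    assert mean == pytest.approx(obs.mean(), rel=1e-12)
    assert err > 0


def test_reweighting_invariant_to_constant_bias_shift(double_well):
    """Adding any constant to the recorded bias leaves the reweighted
    mean unchanged (the constant cancels in the weight ratio)."""
    traj = metropolis_sample(double_well, 20_000, seed=4)
    obs = traj.frames[:, 0] ** 2
    base, _ = reweight_observable(traj, obs, 300.0)
    for shift in (13.7, -4.2, 250.0):
        shifted = TorsionTrajectory(traj.torsion_names, traj.frames,
                                    bias_energy=traj.bias_energy + shift)
        mean, _ = reweight_observable(shifted, obs, 300.0)
        assert mean == pytest.approx(base, rel=1e-9)


def test_two_state_reweighted_population_ratio():
    """Frames visited 50/50 under biases 0 and kBT*ln(3) reweight to a
    3:1 population ratio."""
    kbt = KB * 300.0
    n = 1000
    frames = np.concatenate([np.full(n, -90.0), np.full(n, 90.0)])
    bias = np.concatenate([np.zeros(n), np.full(n, kbt * np.log(3.0))])
    traj = TorsionTrajectory(("phi",), frames[:, None], bias_energy=bias)
    w = reweight_weights(traj, 300.0)
    p_hi = w[frames > 0].sum() / w.sum()
    assert p_hi / (1 - p_hi) == pytest.approx(3.0, rel=1e-12)


def test_reweight_rejects_bad_input(double_well):
    traj = metropolis_sample(double_well, 1_000, seed=1)
    with pytest.raises(ValueError, match="length"):
        reweight_observable(traj, np.ones(3), 300.0)
    bad = np.ones(traj.n_frames)
    bad[5] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        reweight_observable(traj, bad, 300.0)


# ---------------------------------------------------------------------------
# Free-energy maps
# ---------------------------------------------------------------------------

def test_uniform_samples_give_flat_map():
    rng = np.random.default_rng(11)
    n = 400_000
    frames = rng.uniform(-180.0, 180.0, size=(n, 1))
    traj = TorsionTrajectory(("phi",), frames)
    fmap = free_energy_map(traj, LEGridSpec(("phi",)), 300.0)
    kbt = KB * 300.0
    # binomial error on each bin probability propagated to G; the map is
    # min-shifted, so deviations are judged about the mean level
    sigma_g = kbt * np.sqrt((1 - 1 / 36) * 36 / n)
    assert not fmap.mask.any()
    dev = fmap.g - fmap.g.mean()
    assert np.abs(dev).max() < 3 * sigma_g


def test_two_bin_ratio_gives_kbt_ln3():
    frames = np.concatenate([np.full(300, -90.0), np.full(100, 90.0)])
    traj = TorsionTrajectory(("phi",), frames[:, None])
    fmap = free_energy_map(traj, LEGridSpec(("phi",)), 300.0)
    visited = np.nonzero(~fmap.mask)[0]
    dg = np.nanmax(fmap.g[visited])
    assert dg == pytest.approx(KB * 300.0 * np.log(3.0), rel=1e-9)
    assert dg == pytest.approx(2.74, abs=0.01)


def test_map_minimum_zero_and_unvisited_masked():
    frames = np.full((50, 1), 10.0)
    fmap = free_energy_map(TorsionTrajectory(("phi",), frames),
                           LEGridSpec(("phi",)), 300.0)
    assert fmap.mask.sum() == 35
    assert np.nanmin(fmap.g) == 0.0
    assert np.isnan(fmap.g[fmap.mask]).all()


def test_leus_end_to_end_matches_quadrature_1d(leus_1d):
    """Build -> freeze -> sample -> reweight recovers the exact Boltzmann
    free-energy profile of the double well within 0.5 kJ/mol."""
    traj = leus_1d["trajectory"]
    grid = leus_1d["grid"]
    fmap = free_energy_map(traj, grid, 300.0)
    g_exact = exact_bin_free_energy(leus_1d["potential"], ("phi",), grid,
                                    300.0)
    assert not fmap.mask.any()
    assert np.nanmax(np.abs(fmap.g - g_exact)) < 0.5


def test_map_csv_round_trip(leus_1d, tmp_path):
    import pandas as pd

    fmap = free_energy_map(leus_1d["trajectory"], leus_1d["grid"], 300.0)
    path = tmp_path / "gmap.csv"
    fmap.to_csv(path)
    df = pd.read_csv(path)
    assert len(df) == 36
    assert np.allclose(df["G"].to_numpy(), fmap.g, equal_nan=True)


def test_empty_trajectory_rejected():
    with pytest.raises(ValueError):
        TorsionTrajectory(("phi",), np.empty((0, 1)))
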