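"""Structure tools: torsions, Daura clustering vs brute force,
Cremer-Pople puckering, decamer enumeration."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from polysia.ensemble import Atom, ConformerEnsemble
from polysia.geometry import rmsd_after_fit
from polysia.structure import (cluster_daura, cremer_pople,
                               enumerate_decamer_starts, measure_torsion,
                               rmsd_matrix)


def test_measure_torsion_cis_trans_convention():
    a = np.array([0.1, 0.1, 0.0])
    b = np.array([0.0, 0.0, 0.0])
    c = np.array([0.2, 0.0, 0.0])
    d_cis = np.array([0.3, 0.1, 0.0])
    d_trans = np.array([0.3, -0.1, 0.0])
    assert measure_torsion(a, b, c, d_cis) == pytest.approx(0.0, abs=1e-9)
    # trans wraps onto the half-open interval as -180
    assert measure_torsion(a, b, c, d_trans) == pytest.approx(-180.0,
                                                              abs=1e-9)


def test_measure_torsion_rejects_collinear():
    with pytest.raises(ValueError, match="collinear"):
        measure_torsion([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _cloud_ensemble(frames: np.ndarray) -> ConformerEnsemble:
    atoms = [Atom(f"C{i+1}", 1, "C") for i in range(frames.shape[1])]
    return ConformerEnsemble(atoms, frames, [])


def _reference_cloud(rng, n_atoms=5):
    return rng.normal(scale=0.3, size=(n_atoms, 3))


def test_identical_frames_form_one_cluster():
    rng = np.random.default_rng(0)
    base = _reference_cloud(rng)
    ens = _cloud_ensemble(np.stack([base] * 7))
    res = cluster_daura(ens, cutoff=0.1)
    assert res.n_clusters == 1
    assert res.clusters[0] == list(range(7))
    assert res.centers == [0]


def test_all_distant_frames_are_singletons():
    rng = np.random.default_rng(1)
    frames = np.stack([_reference_cloud(rng) + 10.0 * k
                       for k in range(6)])
    res = cluster_daura(_cloud_ensemble(frames), cutoff=0.05)
    assert res.n_clusters == 6
    assert all(len(c) == 1 for c in res.clusters)


def _brute_force_daura(matrix: np.ndarray, cutoff: float):
    """Literal transcription of the algorithm, run on the full matrix."""
    within = matrix < cutoff
    np.fill_diagonal(within, False)
    remaining = set(range(len(matrix)))
    clusters, centers = [], []
    while remaining:
        best, best_n = None, -1
        for i in sorted(remaining):
            n = sum(1 for j in remaining if within[i, j])
            if n > best_n:
                best, best_n = i, n
        members = sorted({best} | {j for j in remaining if within[best, j]})
        clusters.append(members)
        centers.append(best)
        remaining -= set(members)
    return clusters, centers


def _two_blob_ensemble():
    """20 frames: two 9-frame blobs of distinct internal shape plus two
    isolated outliers (RMSD is measured after superposition, so the
    shapes themselves must differ, not just their placement)."""
    rng = np.random.default_rng(3)
    base1 = _reference_cloud(rng)
    base2 = _reference_cloud(rng)
    out1 = _reference_cloud(rng) * 2.0
    out2 = _reference_cloud(rng) * 3.0
    frames = ([base1 + rng.normal(scale=0.01, size=base1.shape)
               for _ in range(9)]
              + [base2 + rng.normal(scale=0.01, size=base1.shape)
                 for _ in range(9)]
              + [out1, out2])
    return _cloud_ensemble(np.stack(frames))


def test_two_blobs_and_outliers_match_brute_force():
    ens = _two_blob_ensemble()
    cutoff = 0.15
    res = cluster_daura(ens, cutoff)
    ref_clusters, ref_centers = _brute_force_daura(rmsd_matrix(ens), cutoff)
    assert res.n_clusters == 4
    assert res.clusters == ref_clusters
    assert res.centers == ref_centers
    assert sorted(len(c) for c in res.clusters) == [1, 1, 9, 9]


def test_partition_covers_all_frames_once():
    ens = _two_blob_ensemble()
    res = cluster_daura(ens, cutoff=0.15)
    members = sorted(itertools.chain.from_iterable(res.clusters))
    assert members == list(range(ens.n_frames))


def test_clustering_invariant_under_frame_reordering():
    ens = _two_blob_ensemble()
    res = cluster_daura(ens, cutoff=0.15)
    perm = np.random.default_rng(9).permutation(ens.n_frames)
    permuted = ConformerEnsemble(ens.atoms, ens.coords[perm], ens.bonds)
    res_p = cluster_daura(permuted, cutoff=0.15)
    # same partition up to relabeling through the permutation
    orig = {frozenset(c) for c in res.clusters}
    back = {frozenset(int(perm[i]) for i in c) for c in res_p.clusters}
    assert orig == back


def test_superposition_never_increases_rmsd():
    rng = np.random.default_rng(5)
    a = _reference_cloud(rng, 8)
    rot = Rotation.from_euler("xyz", [40.0, -10.0, 77.0], degrees=True)
    b = rot.apply(a) + rng.normal(scale=0.05, size=a.shape) + 1.0
    raw = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    fitted = rmsd_after_fit(a, b)
    assert fitted <= raw + 1e-12
    # exact rigid copies superpose to zero
    assert rmsd_after_fit(a, rot.apply(a) + 3.0) < 1e-9


def test_empty_selection_rejected(dimer_frame):
    with pytest.raises(ValueError, match="selection"):
        cluster_daura(dimer_frame, cutoff=0.1, selection=[])


# ---------------------------------------------------------------------------
# Cremer-Pople puckering
# ---------------------------------------------------------------------------

def _hexagon(radius=0.15):
    ang = np.radians(60.0 * np.arange(6))
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(6)])


def test_planar_hexagon_has_zero_amplitude():
    p = cremer_pople(_hexagon())
    assert p.Q == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("updown", [+1, -1])
def test_ideal_chair_theta_is_polar(updown):
    ring = _hexagon()
    ring[:, 2] = updown * 0.025 * np.array([1, -1, 1, -1, 1, -1])
    p = cremer_pople(ring)
    assert min(abs(p.theta), abs(180.0 - p.theta)) < 1e-3
    assert p.Q == pytest.approx(np.sqrt(6) * 0.025, rel=1e-9)


def test_twist_boat_theta_90():
    """Pure m = 2 displacement pattern: the analytic twist-boat/boat
    family sits on the puckering equator."""
    ring = _hexagon()
    ang = 2 * np.pi * np.arange(6) / 6
    for phase in (0.0, 30.0, 90.0):
        ring[:, 2] = 0.025 * np.cos(2 * ang + np.radians(phase))
        p = cremer_pople(ring)
        assert p.theta == pytest.approx(90.0, abs=2.0)
        assert p.Q > 0


def test_pucker_invariant_under_rigid_motion():
    ring = _hexagon()
    ring[:, 2] = 0.02 * np.array([1, -1, 1, -1, 1, -1])
    p0 = cremer_pople(ring)
    rot = Rotation.from_euler("xyz", [12.0, 133.0, -78.0], degrees=True)
    p1 = cremer_pople(rot.apply(ring) + np.array([4.0, -1.0, 2.5]))
    assert p1.Q == pytest.approx(p0.Q, rel=1e-9)
    assert p1.theta == pytest.approx(p0.theta, abs=1e-6)


def test_cyclic_relabeling_shifts_phase_keeps_amplitude():
    ring = _hexagon()
    ang = 2 * np.pi * np.arange(6) / 6
    ring[:, 2] = 0.02 * np.cos(2 * ang + 0.4)
    p0 = cremer_pople(ring)
    shifted = np.roll(ring, -2, axis=0)  # relabel starting two atoms later
    p1 = cremer_pople(shifted)
    assert p1.Q == pytest.approx(p0.Q, rel=1e-9)
    assert p1.theta == pytest.approx(p0.theta, abs=1e-6)
    expected_phi = (p0.phi + 2 * 120.0) % 360.0
    assert p1.phi == pytest.approx(expected_phi, abs=1e-6)


def test_wrong_ring_size_rejected():
    with pytest.raises(ValueError, match="six"):
        cremer_pople(np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# Decamer enumeration
# ---------------------------------------------------------------------------

STATE_A, STATE_B, STATE_C = (60.0, 120.0), (-60.0, -120.0), (160.0, -60.0)


def test_three_states_per_linkage_give_81_structures():
    starts = enumerate_decamer_starts([[STATE_A, STATE_B, STATE_C]] * 4,
                                      build=False)
    assert len(starts) == 81
    assert len({s.pentamer_states for s in starts}) == 81


def test_single_state_gives_one_structure():
    starts = enumerate_decamer_starts([[STATE_B]] * 4, build=False)
    assert len(starts) == 1
    assert starts[0].settings == [STATE_B] * 9


def test_two_states_three_varied_linkages_give_eight():
    states = [[STATE_A, STATE_B], [STATE_A, STATE_B], [STATE_A, STATE_B],
              [STATE_A]]
    assert len(enumerate_decamer_starts(states, build=False)) == 8


def test_periodic_propagation_to_nine_linkages():
    starts = enumerate_decamer_starts(
        [[STATE_A], [STATE_B], [STATE_C], [STATE_A]], build=False)
    s = starts[0].settings
    assert s == [STATE_A, STATE_B, STATE_C, STATE_A] * 2 + [STATE_A]


def test_clash_flags_and_energy_ranking(leus_1d):
    """Built starts carry clash flags; with a map supplied the list is
    ranked by summed interpolated linkage free energies."""
    from polysia.leus import LEGridSpec, free_energy_map
    from polysia.potentials import build_model_potential
    from polysia.sampling import metropolis_sample

    pot = build_model_potential("dimer1_like")
    traj = metropolis_sample(pot, 150_000, seed=77, save_stride=5)
    fmap = free_energy_map(traj, LEGridSpec(("phi", "psi")), 300.0)
    starts = enumerate_decamer_starts([[STATE_A, STATE_B]] * 4,
                                      phi_psi_map=fmap, build=True)
    assert len(starts) == 16
    energies = [s.energy for s in starts]
    assert energies == sorted(energies)
    assert any(not s.clash for s in starts)
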