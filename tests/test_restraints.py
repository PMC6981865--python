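"""Restraint energies: harmonic forms, wrap invariance, the soft bond
and its lambda-derivative, additivity, file round trip."""

import numpy as np
import pytest

from polysia.ensemble import Atom, ConformerEnsemble
from polysia.restraints import (DihedralRestraint, DistanceRestraint,
                                SoftBondRestraint, read_restraint_file,
                                restraint_energy, soft_bond_dHdlambda,
                                soft_bond_energy, total_restraint_energy,
                                write_restraint_file)

PAPER_SB = SoftBondRestraint((1, "A"), (2, "B"))  # kA=0, kB=5e4, r0=0.25, a=250


def _pair_ensemble(distance: float) -> ConformerEnsemble:
    atoms = [Atom("A", 1, "O"), Atom("B", 2, "O")]
    coords = np.array([[[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]])
    return ConformerEnsemble(atoms, coords, [])


def test_distance_restraint_zero_at_reference():
    r = DistanceRestraint((1, "A"), (2, "B"), r0=0.3, k=500.0)
    assert restraint_energy(_pair_ensemble(0.3), 0, r) == pytest.approx(0.0)


def test_full_harmonic_energy_value():
    """k = 500, deviation 0.1 nm: 1/2 * 500 * 0.01 = 2.5 kJ/mol."""
    r = DistanceRestraint((1, "A"), (2, "B"), r0=0.3, k=500.0, style="full")
    assert restraint_energy(_pair_ensemble(0.4), 0, r) == pytest.approx(2.5)
    # full style also penalizes below the reference
    assert restraint_energy(_pair_ensemble(0.2), 0, r) == pytest.approx(2.5)


def test_half_harmonic_is_upper_bound_only():
    r = DistanceRestraint((1, "A"), (2, "B"), r0=0.3, k=500.0, style="half")
    assert restraint_energy(_pair_ensemble(0.25), 0, r) == 0.0
    assert restraint_energy(_pair_ensemble(0.4), 0, r) == pytest.approx(2.5)


def _square_ensemble(chi: float) -> ConformerEnsemble:
    """Four atoms realizing a torsion of chi degrees."""
    from polysia.geometry import place_atom

    a = np.array([0.0, 0.1, 0.0])
    b = np.array([0.0, 0.0, 0.0])
    c = np.array([0.15, 0.0, 0.0])
    d = place_atom(a, b, c, 0.15, 109.47, chi)
    atoms = [Atom(n, 1, "C") for n in ("A1", "A2", "A3", "A4")]
    return ConformerEnsemble(atoms, np.array([[a, b, c, d]]), [])


def test_dihedral_restraint_wrap_invariance():
    """A wrapped deviation of -350 degrees is the same 10-degree
    violation: 1/2 * 100 * 10^2 = 5000 kJ/mol either way."""
    r1 = DihedralRestraint(((1, "A1"), (1, "A2"), (1, "A3"), (1, "A4")),
                           target=80.0, k=100.0)
    ens = _square_ensemble(90.0)
    assert restraint_energy(ens, 0, r1) == pytest.approx(5000.0, rel=1e-9)
    r2 = DihedralRestraint(((1, "A1"), (1, "A2"), (1, "A3"), (1, "A4")),
                           target=80.0 + 360.0 * 2, k=100.0)
    assert restraint_energy(ens, 0, r2) == pytest.approx(
        restraint_energy(ens, 0, r1), rel=1e-12)


def test_unresolvable_atoms_raise(dimer_frame):
    r = DistanceRestraint((1, "XX"), (2, "C2"), r0=0.3, k=500.0)
    with pytest.raises(KeyError):
        restraint_energy(dimer_frame, 0, r)


# ---------------------------------------------------------------------------
# Soft bond
# ---------------------------------------------------------------------------

def test_soft_bond_endpoint_limits():
    # lambda = 0 with kA = 0: zero for any separation
    for r in (0.05, 0.25, 1.0, 3.0):
        assert soft_bond_energy(r, 0.0, PAPER_SB) == 0.0
    # lambda = 1: the softness factor S_B(r, 0) = 1, plain harmonic
    assert soft_bond_energy(0.25, 1.0, PAPER_SB) == 0.0
    for r in (0.2, 0.3, 0.5):
        expected = 0.5 * PAPER_SB.k_b * (r - PAPER_SB.r0_b) ** 2
        assert soft_bond_energy(r, 1.0, PAPER_SB) == pytest.approx(
            expected, rel=1e-12)


def test_soft_bond_midpoint_against_symbolic_oracle():
    """Frozen value from an independent symbolic evaluation of the
    soft-bond expression at lambda = 0.5, r = 0.35 nm."""
    assert soft_bond_energy(0.35, 0.5, PAPER_SB) == pytest.approx(
        55.55555555555556, rel=1e-12)
    assert soft_bond_dHdlambda(0.35, 0.5, PAPER_SB) == pytest.approx(
        172.8395061728395, rel=1e-12)


def test_dhdlambda_matches_central_finite_difference():
    rng = np.random.default_rng(42)
    h = 1e-6
    for _ in range(20):
        r = rng.uniform(0.05, 1.5)
        lam = rng.uniform(h, 1.0 - h)
        fd = (soft_bond_energy(r, lam + h, PAPER_SB)
              - soft_bond_energy(r, lam - h, PAPER_SB)) / (2 * h)
        ana = soft_bond_dHdlambda(r, lam, PAPER_SB)
        assert ana == pytest.approx(fd, rel=1e-5, abs=1e-6)


def test_zero_force_constants_give_zero_derivative():
    sb = SoftBondRestraint((1, "A"), (2, "B"), k_a=0.0, k_b=0.0)
    for r, lam in [(0.1, 0.0), (0.5, 0.5), (2.0, 1.0)]:
        assert soft_bond_dHdlambda(r, lam, sb) == 0.0


def test_derivative_bounded_at_lambda_zero():
    """The softness keeps dH/dlambda finite (and bounded) at lambda = 0
    for arbitrarily large separations — the soft bond's purpose."""
    bound = PAPER_SB.k_b / PAPER_SB.alpha  # asymptotic ceiling
    for r in (0.3, 1.0, 10.0, 1e3):
        d = soft_bond_dHdlambda(r, 0.0, PAPER_SB)
        assert np.isfinite(d)
        assert 0.0 <= d <= bound * 1.01


def test_energy_c1_in_lambda():
    """No kinks along lambda: central differences of dH/dlambda stay
    consistent over a fine scan."""
    lams = np.linspace(0.01, 0.99, 197)
    r = 0.4
    e = np.array([soft_bond_energy(r, l, PAPER_SB) for l in lams])
    d = np.array([soft_bond_dHdlambda(r, l, PAPER_SB) for l in lams])
    fd = np.gradient(e, lams)
    assert np.abs(fd[2:-2] - d[2:-2]).max() < 0.05 * np.abs(d).max()


def test_lambda_out_of_range_rejected():
    with pytest.raises(ValueError):
        soft_bond_energy(0.3, -0.1, PAPER_SB)
    with pytest.raises(ValueError):
        soft_bond_dHdlambda(0.3, 1.2, PAPER_SB)


# ---------------------------------------------------------------------------
# Totals, rigid-motion invariance, file round trip
# ---------------------------------------------------------------------------

def test_total_is_exact_sum_of_breakdown(tetramer_frame):
    """An 82 + 3 + 2 mixed set on a built tetramer: the reported total
    equals the independent per-term re-evaluation."""
    rng = np.random.default_rng(7)
    restraints = []
    names = ("H6", "H7", "H8", "HN5", "HO7", "HO9")
    for _ in range(82):  # NOE-style upper bounds on random proton pairs
        r1, r2 = rng.integers(1, 5, size=2)
        n1, n2 = rng.choice(names, size=2, replace=True)
        if (r1, n1) == (r2, n2):
            n2 = "HO4"
        restraints.append(DistanceRestraint((int(r1), n1), (int(r2), n2),
                                            r0=0.35, k=500.0, style="half"))
    for i in (1, 2, 3):  # H-bond restraints HN5(i+1)-O8(i)
        restraints.append(DistanceRestraint((i + 1, "HN5"), (i, "O8"),
                                            r0=0.25, k=2500.0, style="full"))
    for i in (2, 3):     # W-coupling dihedral restraints
        restraints.append(DihedralRestraint(
            ((i, "H7"), (i, "C7"), (i, "C6"), (i, "H6")), 90.0, 100.0))
    total, breakdown = total_restraint_energy(tetramer_frame, 0, restraints)
    assert len(breakdown) == 87
    assert total == pytest.approx(sum(breakdown), rel=1e-15)
    independent = sum(restraint_energy(tetramer_frame, 0, r)
                      for r in restraints)
    assert total == pytest.approx(independent, rel=1e-12)


def test_empty_and_singleton_sets(tetramer_frame):
    assert total_restraint_energy(tetramer_frame, 0, [])[0] == 0.0
    r = DistanceRestraint((1, "O8"), (2, "HN5"), r0=0.25, k=2500.0)
    total, breakdown = total_restraint_energy(tetramer_frame, 0, [r])
    assert total == pytest.approx(restraint_energy(tetramer_frame, 0, r))
    assert breakdown == [total]


def test_restraint_energy_invariant_under_rigid_motion(dimer_frame):
    from scipy.spatial.transform import Rotation

    restraints = [
        DistanceRestraint((1, "O8"), (2, "HN5"), r0=0.25, k=2500.0),
        DihedralRestraint(((1, "H7"), (1, "C7"), (1, "C6"), (1, "H6")),
                          90.0, 100.0),
        SoftBondRestraint((1, "O8"), (2, "HN5")),
    ]
    before = [restraint_energy(dimer_frame, 0, r, lam=0.7)
              for r in restraints]
    rot = Rotation.from_euler("zyx", [17.0, 123.0, -55.0], degrees=True)
    moved = ConformerEnsemble(
        dimer_frame.atoms,
        rot.apply(dimer_frame.coords[0]) + np.array([0.3, -1.2, 7.0]),
        dimer_frame.bonds)
    after = [restraint_energy(moved, 0, r, lam=0.7) for r in restraints]
    assert np.allclose(before, after, rtol=1e-9, atol=1e-9)


def test_restraint_file_round_trip(tmp_path):
    restraints = [
        DistanceRestraint((1, "O8"), (2, "HN5"), r0=0.25, k=2500.0,
                          style="full"),
        DistanceRestraint((2, "H8"), (3, "H6"), r0=0.35, k=500.0,
                          style="half"),
        DihedralRestraint(((2, "H7"), (2, "C7"), (2, "C6"), (2, "H6")),
                          90.0, 100.0),
        SoftBondRestraint((1, "O8"), (2, "HN5")),
    ]
    path = tmp_path / "restraints.txt"
    write_restraint_file(path, restraints)
    back = read_restraint_file(path)
    assert back == restraints


def test_restraint_file_parse_errors(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("wobble 1:A 2:B 0.1\n")
    with pytest.raises(ValueError, match="unknown restraint type"):
        read_restraint_file(path)


def test_parameter_validation():
    with pytest.raises(ValueError):
        DistanceRestraint((1, "A"), (2, "B"), r0=-0.1, k=500.0)
    with pytest.raises(ValueError):
        DistanceRestraint((1, "A"), (2, "B"), r0=0.1, k=500.0, style="soft")
    with pytest.raises(ValueError):
        DihedralRestraint(((1, "A"), (1, "B"), (1, "C")), 0.0, 1.0)
    with pytest.raises(ValueError):
        SoftBondRestraint((1, "A"), (2, "B"), alpha=-1.0)
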