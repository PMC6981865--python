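"""Idealized 3D builder for alpha-(2->8)-linked sialic-acid-like fragments.

Residues are pyranose-like rings (C2-C3-C4-C5-C6-O6) in a 2C5-type chair
with the glycerol side arm C7-C8-C9 on C6, the carboxylate C1(O1A/O1B)
and anomeric oxygen on C2, the N-acetyl nitrogen on C5 and the hydroxyl
protons needed as hydrogen-bond donors.  Geometry uses fixed ideal
internal coordinates (C-C 0.153 nm, C-O 0.143 nm, tetrahedral angles) —
only relative geometry matters for the observables computed downstream.

Chains are grown from the reducing end (residue 1, label "a"): residue
i+1 is attached through its anomeric carbon to O8 of residue i, with the
glycosidic torsions phi = O6'-C2'-O8-C8 and psi = C2'-O8-C8-C7 set
exactly to the requested values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .ensemble import Atom, ConformerEnsemble
from .geometry import (TETRAHEDRAL_ANGLE, measure_angle, place_atom,
                       rigid_transform_from_points, tetrahedral_directions)

# ideal internal coordinates, nm
BOND_CC = 0.153
BOND_CO = 0.143
BOND_CH = 0.109
BOND_OH = 0.100
BOND_NH = 0.100
BOND_CN = 0.147
BOND_C_OCARB = 0.125  # carboxylate C-O
RING_BOND = 0.150     # uniform ring bond (idealized mix of C-C and C-O)

FRAGMENT_SIZES = {"monomer": 1, "dimer": 2, "trimer": 3, "tetramer": 4,
                  "decamer": 10}

DEFAULT_SIDE_TORSIONS = {"omega7": 60.0, "omega8": 60.0, "omega9": -60.0}

RING_NAMES = ("C2", "C3", "C4", "C5", "C6", "O6")


def _chair_ring() -> dict[str, np.ndarray]:
    """Closed six-ring in an ideal chair (alternating +/-q displacement)
    with uniform bond length RING_BOND and near-tetrahedral angles."""

    def vertex(k: int, q: float) -> np.ndarray:
        rho = np.sqrt(RING_BOND ** 2 - 4.0 * q * q)
        ang = np.radians(60.0 * k)
        return np.array([rho * np.cos(ang), rho * np.sin(ang),
                         q if k % 2 == 0 else -q])

    def angle_err(q: float) -> float:
        v0, v1, v2 = vertex(0, q), vertex(1, q), vertex(2, q)
        return measure_angle(v0, v1, v2) - TETRAHEDRAL_ANGLE

    q = brentq(angle_err, 1e-6, RING_BOND / 2 - 1e-6)
    return {name: vertex(k, q) for k, name in enumerate(RING_NAMES)}


_RING = _chair_ring()


def _exocyclic(ring: dict[str, np.ndarray], name: str) -> tuple[np.ndarray, np.ndarray]:
    """(axial, equatorial) unit directions at a ring atom.

    Axial is the completion direction whose z sign matches the vertex's
    own chair displacement.
    """
    k = RING_NAMES.index(name)
    prev_ = ring[RING_NAMES[(k - 1) % 6]]
    next_ = ring[RING_NAMES[(k + 1) % 6]]
    d1, d2 = tetrahedral_directions(ring[name], prev_, next_)
    z = ring[name][2]
    if np.sign(d1[2]) == np.sign(z):
        return d1, d2
    return d2, d1


@dataclass
class _Residue:
    names: list[str]
    coords: dict[str, np.ndarray]
    bonds: list[tuple[str, str]]
    olink: np.ndarray  # anomeric-oxygen position (virtual for linked residues)


def _build_residue(side: dict[str, float], anomer: str = "alpha",
                   reducing: bool = False,
                   free_o8: bool = True) -> _Residue:
    """One residue in its local frame, with exact side-chain torsions."""
    if anomer not in ("alpha", "beta"):
        raise ValueError(f"anomer must be 'alpha' or 'beta', got {anomer!r}")
    w7 = side.get("omega7", DEFAULT_SIDE_TORSIONS["omega7"])
    w8 = side.get("omega8", DEFAULT_SIDE_TORSIONS["omega8"])
    w9 = side.get("omega9", DEFAULT_SIDE_TORSIONS["omega9"])

    ring = {k: v.copy() for k, v in _RING.items()}
    pos = dict(ring)
    bonds = [(RING_NAMES[i], RING_NAMES[(i + 1) % 6]) for i in range(6)]

    def put(name, a, b, c, bond, torsion, angle=TETRAHEDRAL_ANGLE):
        pos[name] = place_atom(pos[a], pos[b], pos[c], bond, angle, torsion)
        bonds.append((c, name))

    # anomeric center C2: carboxylate + anomeric oxygen
    ax, eq = _exocyclic(ring, "C2")
    o_dir, c1_dir = (ax, eq) if anomer == "alpha" else (eq, ax)
    olink = pos["C2"] + BOND_CO * o_dir
    pos["C1"] = pos["C2"] + BOND_CC * c1_dir
    bonds.append(("C2", "C1"))
    put("O1A", "C3", "C2", "C1", BOND_C_OCARB, 0.0, angle=120.0)
    put("O1B", "C3", "C2", "C1", BOND_C_OCARB, 180.0, angle=120.0)
    if reducing:
        pos["O2"] = olink
        bonds.append(("C2", "O2"))
        put("HO2", "C1", "C2", "O2", BOND_OH, 180.0)

    # C4 hydroxyl, C5 N-acetyl (simplified to N-CH3)
    _, eq4 = _exocyclic(ring, "C4")
    pos["O4"] = pos["C4"] + BOND_CO * eq4
    bonds.append(("C4", "O4"))
    put("HO4", "C3", "C4", "O4", BOND_OH, 180.0)
    _, eq5 = _exocyclic(ring, "C5")
    pos["N5"] = pos["C5"] + BOND_CN * eq5
    bonds.append(("C5", "N5"))
    # torsions chosen to keep the simplified N-acetyl clear of the ring
    # substituents and the glycerol arm for any side-chain rotamer
    put("HN5", "C4", "C5", "N5", BOND_NH, -60.0, angle=120.0)
    put("C5A", "C4", "C5", "N5", BOND_CN, 40.0, angle=120.0)

    # glycerol arm on C6; H6 axial, chain equatorial
    ax6, eq6 = _exocyclic(ring, "C6")
    pos["C7"] = pos["C6"] + BOND_CC * eq6
    bonds.append(("C6", "C7"))
    pos["H6"] = pos["C6"] + BOND_CH * ax6
    bonds.append(("C6", "H6"))
    put("O7", "O6", "C6", "C7", BOND_CO, w7)           # omega7 exact
    put("C8", "O6", "C6", "C7", BOND_CC, w7 + 120.0)
    put("H7", "O6", "C6", "C7", BOND_CH, w7 - 120.0)
    put("HO7", "C8", "C7", "O7", BOND_OH, 180.0)
    put("O8", "O7", "C7", "C8", BOND_CO, w8)           # omega8 exact
    put("C9", "O7", "C7", "C8", BOND_CC, w8 + 120.0)
    put("H8", "O7", "C7", "C8", BOND_CH, w8 - 120.0)
    put("O9", "O8", "C8", "C9", BOND_CO, w9)           # omega9 exact
    put("HO9", "C8", "C9", "O9", BOND_OH, 180.0)
    if free_o8:
        put("HO8", "C7", "C8", "O8", BOND_OH, 180.0)

    order = [n for n in (
        "C1", "O1A", "O1B", "C2", "O2", "HO2", "C3", "C4", "O4", "HO4",
        "C5", "N5", "HN5", "C5A", "C6", "H6", "O6", "C7", "H7", "O7",
        "HO7", "C8", "H8", "O8", "HO8", "C9", "O9", "HO9",
    ) if n in pos]
    return _Residue(order, pos, bonds, olink)


UNITED_CARBONS = {"C3": "CH2", "C4": "CH", "C5": "CH", "C6": "CH",
                  "C7": "CH", "C8": "CH", "C9": "CH2", "C5A": "CH3"}


def build_fragment(kind: str, glycosidic_settings=None, side_torsions=None,
                   anomer: str = "alpha") -> ConformerEnsemble:
    """Build a single-frame oligomer with prescribed glycosidic torsions.

    Parameters
    ----------
    kind : one of monomer, dimer, trimer, tetramer, decamer.
    glycosidic_settings : sequence of (phi, psi) pairs, one per linkage
        (linkage i joins residue i+1's anomeric carbon to residue i's O8).
    side_torsions : optional dict or per-residue list of dicts with keys
        omega7/omega8/omega9 (degrees).
    anomer : anomeric configuration of the reducing-end residue.

    The built frame reproduces every requested torsion exactly (well
    within the 1-degree contract).  Steric clashes (non-bonded pairs
    closer than 0.08 nm) are flagged on the returned ensemble's
    ``clash_pairs`` attribute, not raised.
    """
    if kind not in FRAGMENT_SIZES:
        raise ValueError(f"unknown fragment kind {kind!r}; "
                         f"choose from {sorted(FRAGMENT_SIZES)}")
    n_res = FRAGMENT_SIZES[kind]
    n_link = n_res - 1
    settings = list(glycosidic_settings or [])
    if len(settings) != n_link:
        raise ValueError(
            f"{kind} has {n_link} linkages; got {len(settings)} "
            "glycosidic settings"
        )
    if side_torsions is None:
        per_res = [dict(DEFAULT_SIDE_TORSIONS)] * n_res
    elif isinstance(side_torsions, dict):
        per_res = [dict(DEFAULT_SIDE_TORSIONS, **side_torsions)] * n_res
    else:
        if len(side_torsions) != n_res:
            raise ValueError("need one side-torsion dict per residue")
        per_res = [dict(DEFAULT_SIDE_TORSIONS, **s) for s in side_torsions]

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    placed: list[dict[str, np.ndarray]] = []

    def add_residue(res: _Residue, resi: int,
                    transform=None) -> dict[str, np.ndarray]:
        offset = len(atoms)
        local = {}
        name_to_idx = {}
        for name in res.names:
            p = res.coords[name]
            if transform is not None:
                p = transform(p)
            el = name[0] if name[0] in "CONH" else "C"
            united = name in UNITED_CARBONS
            atoms.append(Atom(name, resi, el, united))
            coords.append(p)
            name_to_idx[name] = offset + len(name_to_idx)
            local[name] = p
        for a, b in res.bonds:
            if a in name_to_idx and b in name_to_idx:
                bonds.append((name_to_idx[a], name_to_idx[b]))
        return local

    # residue 1 (reducing end) sits in the template frame
    res1 = _build_residue(per_res[0], anomer=anomer, reducing=True,
                          free_o8=(n_res == 1))
    placed.append(add_residue(res1, 1))

    for i in range(n_link):
        phi, psi = settings[i]
        prev = placed[i]
        template = _build_residue(per_res[i + 1], anomer="alpha",
                                  reducing=False,
                                  free_o8=(i == n_link - 1))
        # anchor: C2' from psi, O6' from phi (NeRF), then exact rigid fit
        c2_new = place_atom(prev["C7"], prev["C8"], prev["O8"],
                            BOND_CO, TETRAHEDRAL_ANGLE, psi)
        d_c2_o6 = float(np.linalg.norm(template.coords["C2"]
                                       - template.coords["O6"]))
        o6_new = place_atom(prev["C8"], prev["O8"], c2_new,
                            d_c2_o6, TETRAHEDRAL_ANGLE, phi)
        src = np.array([template.coords["C2"], template.olink,
                        template.coords["O6"]])
        dst = np.array([c2_new, prev["O8"], o6_new])
        transform = rigid_transform_from_points(src, dst)
        new = add_residue(template, i + 2, transform=transform)
        bonds.append((_index_of(atoms, i + 1, "O8"),
                      _index_of(atoms, i + 2, "C2")))
        placed.append(new)

    ens = ConformerEnsemble(atoms, np.asarray(coords), bonds)
    ens.clash_pairs = ens.clashes(0)
    return ens


def _index_of(atoms: list[Atom], resi: int, name: str) -> int:
    for k, a in enumerate(atoms):
        if a.residue_index == resi and a.name == name:
            return k
    raise KeyError((resi, name))


def linkage_torsions(ens: ConformerEnsemble, linkage: int) -> tuple[float, float]:
    """Measured (phi, psi) of linkage ``linkage`` (0-based; joins residue
    linkage+1 to residue linkage+2)."""
    from .geometry import measure_torsion

    i, j = linkage + 1, linkage + 2
    f = 0
    phi = measure_torsion(ens.position(f, j, "O6"), ens.position(f, j, "C2"),
                          ens.position(f, i, "O8"), ens.position(f, i, "C8"))
    psi = measure_torsion(ens.position(f, j, "C2"), ens.position(f, i, "O8"),
                          ens.position(f, i, "C8"), ens.position(f, i, "C7"))
    return phi, psi


def side_chain_torsions(ens: ConformerEnsemble, residue: int,
                        frame: int = 0) -> dict[str, float]:
    """Measured omega7/omega8/omega9 of one residue."""
    from .geometry import measure_torsion

    def t(a, b, c, d):
        return measure_torsion(ens.position(frame, residue, a),
                               ens.position(frame, residue, b),
                               ens.position(frame, residue, c),
                               ens.position(frame, residue, d))

    return {"omega7": t("O7", "C7", "C6", "O6"),
            "omega8": t("O8", "C8", "C7", "O7"),
            "omega9": t("O9", "C9", "C8", "O8")}
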