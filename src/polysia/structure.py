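"""Geometric analyses on conformer ensembles: torsion measurement,
conformational clustering, Cremer-Pople ring puckering and the decamer
start-structure enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble
from .fragments import build_fragment
from .geometry import measure_torsion, rmsd_after_fit

__all__ = ["measure_torsion", "ClusterResult", "rmsd_matrix", "cluster_daura",
           "PuckerCoordinates", "cremer_pople", "DecamerStart",
           "enumerate_decamer_starts"]


# ---------------------------------------------------------------------------
# Daura-style conformational clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Partition of frames into clusters.

    ``clusters`` is a list of frame-index lists, extraction order (first
    cluster had the most neighbors); ``centers[k]`` is the central member
    of cluster k (the frame that maximized the within-cutoff neighbor
    count at extraction time).
    """

    clusters: list[list[int]]
    centers: list[int]
    cutoff: float
    selection: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> np.ndarray:
        n = sum(len(c) for c in self.clusters)
        out = np.empty(n, dtype=int)
        for k, members in enumerate(self.clusters):
            out[members] = k
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": np.arange(self.n_clusters),
            "center_frame": self.centers,
            "size": [len(c) for c in self.clusters],
            "members": [" ".join(map(str, c)) for c in self.clusters],
        })


def heavy_atom_selection(ens: ConformerEnsemble) -> list[int]:
    return [i for i, a in enumerate(ens.atoms) if a.element != "H"]


def rmsd_matrix(ens: ConformerEnsemble, selection=None) -> np.ndarray:
    """Pairwise RMSD (nm) after optimal superposition on the selection."""
    if selection is None:
        selection = heavy_atom_selection(ens)
    selection = list(selection)
    if not selection:
        raise ValueError("empty atom selection")
    xyz = ens.coords[:, selection]
    n = ens.n_frames
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = rmsd_after_fit(xyz[i], xyz[j])
    return m


def cluster_daura(ens: ConformerEnsemble, cutoff: float,
                  selection=None) -> ClusterResult:
    """Iterative neighbor-count clustering on the RMSD matrix.

    Repeatedly the frame with the most remaining neighbors within
    ``cutoff`` seeds a cluster containing itself and those neighbors;
    all are removed and the procedure recurses.  Ties break toward the
    lowest frame index, making the partition deterministic.
    """
    if ens.n_frames < 1:
        raise ValueError("need at least one frame")
    if selection is None:
        selection = heavy_atom_selection(ens)
    selection = list(selection)
    m = rmsd_matrix(ens, selection)
    within = m < cutoff
    np.fill_diagonal(within, False)
    remaining = np.ones(ens.n_frames, dtype=bool)
    clusters: list[list[int]] = []
    centers: list[int] = []
    while remaining.any():
        counts = (within & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero((within[center] & remaining))[0].tolist()
        cluster = sorted([center] + members)
        clusters.append(cluster)
        centers.append(center)
        remaining[cluster] = False
    return ClusterResult(clusters, centers, cutoff, selection)


def write_cluster_centers(ens: ConformerEnsemble, result: ClusterResult,
                          path) -> None:
    """Central members as a multi-MODEL PDB, cluster order."""
    sub = ConformerEnsemble(ens.atoms, ens.coords[result.centers], ens.bonds)
    sub.to_pdb(path)


# ---------------------------------------------------------------------------
# Cremer-Pople ring puckering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PuckerCoordinates:
    """Generalized puckering of a six-ring: total amplitude Q (nm), polar
    angle theta in [0, 180] and phase phi2 in [0, 360) degrees.  A
    planar ring has Q = 0; ideal chairs sit at theta = 0 or 180."""

    Q: float
    theta: float
    phi: float


def cremer_pople(ens_or_coords, ring_atoms=None, frame: int = 0,
                 residue: int | None = None) -> PuckerCoordinates:
    """Cremer-Pople coordinates of a six-membered ring.

    Accepts either an (6, 3) coordinate array, or a ConformerEnsemble
    plus ``residue`` (uses the C2-C3-C4-C5-C6-O6 ring) or explicit
    ``ring_atoms`` [(residue, name), ...] in ring order.
    """
    if isinstance(ens_or_coords, ConformerEnsemble):
        ens = ens_or_coords
        if ring_atoms is None:
            if residue is None:
                raise ValueError("residue index or ring_atoms required")
            ring_atoms = [(residue, n)
                          for n in ("C2", "C3", "C4", "C5", "C6", "O6")]
        xyz = np.array([ens.position(frame, r, n) for r, n in ring_atoms])
    else:
        xyz = np.asarray(ens_or_coords, dtype=float)
    if xyz.shape != (6, 3):
        raise ValueError("need exactly six ring atoms")

    center = xyz.mean(axis=0)
    rel = xyz - center
    n_ring = 6
    ang = 2.0 * np.pi * np.arange(n_ring) / n_ring
    r_a = (rel * np.sin(ang)[:, None]).sum(axis=0)
    r_b = (rel * np.cos(ang)[:, None]).sum(axis=0)
    normal = np.cross(r_a, r_b)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise ValueError("degenerate ring geometry")
    normal /= norm
    z = rel @ normal

    q2c = np.sqrt(2.0 / n_ring) * np.sum(z * np.cos(2 * ang))
    q2s = -np.sqrt(2.0 / n_ring) * np.sum(z * np.sin(2 * ang))
    q3 = np.sum(z * np.cos(ang * 3)) / np.sqrt(n_ring)
    q2 = np.hypot(q2c, q2s)
    big_q = float(np.sqrt(np.sum(z ** 2)))
    theta = float(np.degrees(np.arctan2(q2, q3)))
    phi = float(np.degrees(np.arctan2(q2s, q2c)) % 360.0)
    return PuckerCoordinates(big_q, theta, phi)


def pucker_series(ens: ConformerEnsemble, residue: int) -> pd.DataFrame:
    rows = [cremer_pople(ens, residue=residue, frame=f)
            for f in range(ens.n_frames)]
    return pd.DataFrame({"frame": np.arange(ens.n_frames),
                         "Q": [p.Q for p in rows],
                         "theta": [p.theta for p in rows],
                         "phi": [p.phi for p in rows]})


# ---------------------------------------------------------------------------
# Decamer start-structure enumeration
# ---------------------------------------------------------------------------

@dataclass
class DecamerStart:
    pentamer_states: tuple[tuple[float, float], ...]  # 4 linkage settings
    settings: list[tuple[float, float]]               # propagated to 9 linkages
    clash: bool
    energy: float  # summed per-linkage map free energies (kJ/mol), NaN if no map


def enumerate_decamer_starts(states, phi_psi_map=None, build: bool = True,
                             side_torsions=None) -> list[DecamerStart]:
    """All decamer start structures from per-linkage candidate states.

    ``states``: four sequences of candidate (phi, psi) pairs, one per
    pentamer linkage.  Every combination (Cartesian product; 3 states x 4
    linkages gives 81) is propagated periodically to the nine decamer
    linkages, optionally built in 3D to flag steric clashes, and ranked
    by the summed free energy of its linkage settings interpolated on the
    supplied (phi, psi) map.
    """
    states = [list(s) for s in states]
    if len(states) != 4 or any(len(s) < 1 for s in states):
        raise ValueError("need four non-empty per-linkage state sets")
    out = []
    for combo in itertools.product(*states):
        settings = [combo[i % 4] for i in range(9)]
        clash = False
        if build:
            ens = build_fragment("decamer", settings,
                                 side_torsions=side_torsions)
            clash = bool(ens.clash_pairs)
        if phi_psi_map is not None:
            pts = np.asarray(settings, dtype=float)
            energy = float(np.sum(phi_psi_map.value_at(pts)))
        else:
            energy = float("nan")
        out.append(DecamerStart(tuple(combo), settings, clash, energy))
    if phi_psi_map is not None:
        out.sort(key=lambda s: s.energy)
    return out
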