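"""Elementary 3D geometry: torsion measurement, internal-coordinate atom
placement (NeRF), tetrahedral completion and least-squares superposition."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .units import wrap_angle

TETRAHEDRAL_ANGLE = 109.47122063449069  # arccos(-1/3), degrees


def measure_torsion(p0, p1, p2, p3) -> float:
    """Signed IUPAC torsion angle in degrees, wrapped to [-180, 180).

    Zero for a cis (eclipsed) arrangement; the sign follows the
    right-hand rule looking from p1 to p2.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("torsion undefined: three collinear atoms")
    m = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def measure_angle(p0, p1, p2) -> float:
    """Bond angle at p1 in degrees."""
    v0 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    c = np.dot(v0, v2) / (np.linalg.norm(v0) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C given the chain A-B-C (NeRF construction).

    ``bond`` = |C-D|, ``angle`` = angle(B, C, D) in degrees, ``torsion`` =
    torsion(A, B, C, D) in degrees.  The returned position reproduces the
    three internals exactly.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        -np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("reference atoms are collinear")
    n /= norm
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def tetrahedral_directions(center, neighbor_a, neighbor_b,
                           angle: float = TETRAHEDRAL_ANGLE) -> tuple[np.ndarray, np.ndarray]:
    """The two unit directions completing a tetrahedral center that
    already has two substituents.

    Both returned directions make ``angle`` with each existing bond; they
    are mirror images through the neighbor plane (axial/equatorial, or
    pro-R/pro-S for a CH2).
    """
    c = np.asarray(center, float)
    a = np.asarray(neighbor_a, float) - c
    b = np.asarray(neighbor_b, float) - c
    a /= np.linalg.norm(a)
    b /= np.linalg.norm(b)
    cos_t = np.cos(np.radians(angle))
    gamma = np.dot(a, b)
    alpha = cos_t / (1.0 + gamma)
    w = np.cross(a, b)
    wn = np.linalg.norm(w)
    if wn < 1e-10:
        raise ValueError("degenerate neighbor geometry")
    w /= wn
    base = alpha * (a + b)
    rem = 1.0 - np.dot(base, base)
    if rem < 0:
        raise ValueError(f"no tetrahedral completion for angle {angle}")
    beta = np.sqrt(rem)
    return base + beta * w, base - beta * w


def opposing_direction(center, neighbors) -> np.ndarray:
    """Unit vector opposing the mean of the bond directions (completes a
    CH center with three heavy neighbors)."""
    c = np.asarray(center, float)
    s = np.zeros(3)
    for nb in neighbors:
        v = np.asarray(nb, float) - c
        s += v / np.linalg.norm(v)
    n = np.linalg.norm(s)
    if n < 1e-10:
        raise ValueError("neighbor directions cancel; CH direction undefined")
    return -s / n


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights=None) -> tuple[np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns (transformed coordinates, RMSD after fitting).  Rotation via
    quaternion-based Kabsch (scipy align_vectors), which attains the
    global optimum.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc,
                                    weights=weights)
    moved = rot.apply(mobile - mc) + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, rmsd


def rmsd_after_fit(a: np.ndarray, b: np.ndarray) -> float:
    return superpose(a, b)[1]


def rigid_transform_from_points(src: np.ndarray, dst: np.ndarray):
    """Least-squares rigid map src -> dst; returns ``apply(points)``.

    Exact when the two point sets are congruent (used to graft residue
    templates onto anchor triples).
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - dc, src - sc)

    def apply(points: np.ndarray) -> np.ndarray:
        return rot.apply(np.asarray(points, float) - sc) + dc

    return apply
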