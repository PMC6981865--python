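"""Restraint energy terms: instantaneous harmonic distance and dihedral
restraints and the lambda-coupled soft-bond restraint.

"Instantaneous" means the penalty acts on the current frame only (no
time averaging).  NOE-derived distance restraints default to the
attractive-half-harmonic (upper-bound) style — only violations above the
bound are penalized — while hydrogen-bond distance restraints and
dihedral restraints are full harmonic; both styles are available on
every distance restraint.

The soft bond couples a harmonic restraint to an alchemical parameter
lambda without the singular lambda-derivative a bare (1-lambda)*0 + ...
switch would produce:

    U(r, L) = 1/2 [ (1-L) kA / SA(r, L) + L kB / SB(r, 1-L) ] * (r - r0(L))^2
    SX(r, L) = 1 + alpha * L * (r - r0X)^2,   r0(L) = (1-L) r0A + L r0B

with a unitless softness alpha (default 250).  At L = 0 the derivative
dU/dL = kB (r-r0B)^2 / SB(r, 1) <= kB/alpha stays bounded for any r.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ensemble import ConformerEnsemble
from .geometry import measure_torsion
from .units import wrap_angle_scalar

# force constants of the tetramer restraint protocol
NOE_FORCE_CONSTANT = 500.0        # kJ mol^-1 nm^-2
HBOND_FORCE_CONSTANT = 2500.0     # kJ mol^-1 nm^-2
DIHEDRAL_FORCE_CONSTANT = 100.0   # kJ mol^-1 degree^-2
SOFT_BOND_KB = 5.0e4              # kJ mol^-1 nm^-2
SOFT_BOND_R0 = 0.25               # nm
SOFT_BOND_ALPHA = 250.0


@dataclass(frozen=True)
class DistanceRestraint:
    atom1: tuple[int, str]
    atom2: tuple[int, str]
    r0: float
    k: float
    style: str = "full"  # "full" | "half" (attractive upper bound)

    def __post_init__(self) -> None:
        if self.k < 0 or self.r0 <= 0:
            raise ValueError("need k >= 0 and r0 > 0")
        if self.style not in ("full", "half"):
            raise ValueError(f"unknown style {self.style!r}")


@dataclass(frozen=True)
class DihedralRestraint:
    atoms: tuple[tuple[int, str], ...]
    target: float  # degrees
    k: float       # kJ mol^-1 degree^-2

    def __post_init__(self) -> None:
        if len(self.atoms) != 4:
            raise ValueError("dihedral restraint needs four atoms")
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass(frozen=True)
class SoftBondRestraint:
    atom1: tuple[int, str]
    atom2: tuple[int, str]
    k_a: float = 0.0
    k_b: float = SOFT_BOND_KB
    r0_a: float = SOFT_BOND_R0
    r0_b: float = SOFT_BOND_R0
    alpha: float = SOFT_BOND_ALPHA

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


Restraint = DistanceRestraint | DihedralRestraint | SoftBondRestraint


def _pair_distance(ens: ConformerEnsemble, frame: int, r: Restraint) -> float:
    p1 = ens.position(frame, *r.atom1)
    p2 = ens.position(frame, *r.atom2)
    return float(np.linalg.norm(p1 - p2))


def soft_bond_energy(r: float, lam: float, sb: SoftBondRestraint) -> float:
    """Soft-bond energy (kJ/mol) at separation r (nm) and coupling lam."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    sa = 1.0 + sb.alpha * lam * (r - sb.r0_a) ** 2
    sbx = 1.0 + sb.alpha * (1.0 - lam) * (r - sb.r0_b) ** 2
    d = r - ((1.0 - lam) * sb.r0_a + lam * sb.r0_b)
    return 0.5 * ((1.0 - lam) * sb.k_a / sa + lam * sb.k_b / sbx) * d * d


def soft_bond_dHdlambda(r: float, lam: float, sb: SoftBondRestraint) -> float:
    """Analytic dU/dlambda of the soft bond (kJ/mol)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    da = r - sb.r0_a
    db = r - sb.r0_b
    sa = 1.0 + sb.alpha * lam * da * da
    sbx = 1.0 + sb.alpha * (1.0 - lam) * db * db
    d = r - ((1.0 - lam) * sb.r0_a + lam * sb.r0_b)
    keff = (1.0 - lam) * sb.k_a / sa + lam * sb.k_b / sbx
    dk = (-sb.k_a / sa
          - (1.0 - lam) * sb.k_a * sb.alpha * da * da / sa ** 2
          + sb.k_b / sbx
          + lam * sb.k_b * sb.alpha * db * db / sbx ** 2)
    dd = -(sb.r0_b - sb.r0_a)  # d(d)/dlam = -(dr0/dlam)
    return 0.5 * dk * d * d + keff * d * dd


def restraint_energy(ens: ConformerEnsemble, frame: int, r: Restraint,
                     lam: float = 1.0) -> float:
    """Energy (kJ/mol) of one restraint on one frame."""
    if isinstance(r, DistanceRestraint):
        d = _pair_distance(ens, frame, r)
        dev = d - r.r0
        if r.style == "half" and dev <= 0:
            return 0.0
        return 0.5 * r.k * dev * dev
    if isinstance(r, DihedralRestraint):
        chi = measure_torsion(*(ens.position(frame, *a) for a in r.atoms))
        dev = wrap_angle_scalar(chi - r.target)
        return 0.5 * r.k * dev * dev
    if isinstance(r, SoftBondRestraint):
        return soft_bond_energy(_pair_distance(ens, frame, r), lam, r)
    raise TypeError(f"unknown restraint type {type(r)!r}")


def total_restraint_energy(ens: ConformerEnsemble, frame: int,
                           restraints, lam: float = 1.0):
    """(total, per-restraint breakdown); the breakdown sums to the total
    exactly (plain summation in list order)."""
    breakdown = [restraint_energy(ens, frame, r, lam) for r in restraints]
    return float(sum(breakdown)), breakdown


# ---------------------------------------------------------------------------
# Plain-text restraint files: one restraint per line
# ---------------------------------------------------------------------------

def _fmt_atom(a: tuple[int, str]) -> str:
    return f"{a[0]}:{a[1]}"


def _parse_atom(s: str) -> tuple[int, str]:
    res, name = s.split(":")
    return int(res), name


def write_restraint_file(path: str | Path, restraints) -> None:
    lines = ["# type atoms... parameters"]
    for r in restraints:
        if isinstance(r, DistanceRestraint):
            lines.append(f"distance {_fmt_atom(r.atom1)} {_fmt_atom(r.atom2)} "
                         f"{r.r0:.6g} {r.k:.6g} {r.style}")
        elif isinstance(r, DihedralRestraint):
            atoms = " ".join(_fmt_atom(a) for a in r.atoms)
            lines.append(f"dihedral {atoms} {r.target:.6g} {r.k:.6g}")
        elif isinstance(r, SoftBondRestraint):
            lines.append(f"softbond {_fmt_atom(r.atom1)} {_fmt_atom(r.atom2)} "
                         f"{r.k_a:.6g} {r.k_b:.6g} {r.r0_a:.6g} "
                         f"{r.r0_b:.6g} {r.alpha:.6g}")
        else:
            raise TypeError(f"cannot serialize {type(r)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_restraint_file(path: str | Path) -> list[Restraint]:
    out: list[Restraint] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        kind, *rest = line.split()
        try:
            if kind == "distance":
                a1, a2, r0, k, style = rest
                out.append(DistanceRestraint(_parse_atom(a1), _parse_atom(a2),
                                             float(r0), float(k), style))
            elif kind == "dihedral":
                atoms = tuple(_parse_atom(a) for a in rest[:4])
                out.append(DihedralRestraint(atoms, float(rest[4]),
                                             float(rest[5])))
            elif kind == "softbond":
                a1, a2, ka, kb, r0a, r0b, alpha = rest
                out.append(SoftBondRestraint(_parse_atom(a1), _parse_atom(a2),
                                             float(ka), float(kb), float(r0a),
                                             float(r0b), float(alpha)))
            else:
                raise ValueError(f"unknown restraint type {kind!r}")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln}: cannot parse restraint: {exc}")
    return out
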