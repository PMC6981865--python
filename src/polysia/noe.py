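"""NOE distance averaging and restraint-table I/O.

NOE intensities report the inverse-sixth-power average of the interproton
distance, so the effective distance of an ensemble is

    r_eff = ( sum_i w_i r_i^-6 / sum_i w_i )^(-1/6),

which is always <= the linear average and is dominated by the closest
approaches.  Restraint lists use a plain three-column text format::

    residue:atom  residue:atom  upper_bound_nm

with '#' comments; atom specs like ``2:H8`` or ``b:H8`` (residue letter
or 1-based index).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ensemble import RESIDUE_LABELS, ConformerEnsemble


def noe_average(ensemble: ConformerEnsemble, atom_pair, weights=None) -> float:
    """Effective <r^-6>^(-1/6) distance (nm) of an atom pair.

    ``atom_pair``: ((residue, name), (residue, name)).
    """
    (r1, n1), (r2, n2) = atom_pair
    i = ensemble.index(r1, n1)
    j = ensemble.index(r2, n2)
    d = np.linalg.norm(ensemble.coords[:, i] - ensemble.coords[:, j], axis=1)
    return noe_average_distances(d, weights)


def noe_average_distances(distances, weights=None) -> float:
    d = np.asarray(distances, dtype=float)
    if (d <= 0).any():
        raise ValueError("zero or negative distance in ensemble")
    if weights is None:
        weights = np.ones_like(d)
    w = np.asarray(weights, dtype=float)
    if w.shape != d.shape:
        raise ValueError("weights length must match frame count")
    return float((np.sum(w * d ** -6) / np.sum(w)) ** (-1.0 / 6.0))


@dataclass(frozen=True)
class NOEBound:
    atom1: tuple[int, str]
    atom2: tuple[int, str]
    upper_bound: float  # nm, including any pseudo-atom correction


def _parse_atom_spec(spec: str) -> tuple[int, str]:
    res, name = spec.split(":")
    if res.isdigit():
        return int(res), name
    return RESIDUE_LABELS.index(res.lower()) + 1, name


def read_noe_table(path: str | Path) -> list[NOEBound]:
    bounds = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        a1, a2, ub = line.split()
        bounds.append(NOEBound(_parse_atom_spec(a1), _parse_atom_spec(a2),
                               float(ub)))
    return bounds


def write_noe_table(path: str | Path, bounds) -> None:
    lines = ["# atom1 atom2 upper_bound_nm"]
    for b in bounds:
        lines.append(f"{b.atom1[0]}:{b.atom1[1]} {b.atom2[0]}:{b.atom2[1]} "
                     f"{b.upper_bound:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def noe_report(ensemble: ConformerEnsemble, bounds, weights=None):
    """Per-bound effective distances and violations.

    Returns a list of dicts (bound, r_eff, violation), where violation is
    max(0, r_eff - upper_bound).
    """
    out = []
    for b in bounds:
        r_eff = noe_average(ensemble, (b.atom1, b.atom2), weights)
        out.append({"bound": b, "r_eff": r_eff,
                    "violation": max(0.0, r_eff - b.upper_bound)})
    return out
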