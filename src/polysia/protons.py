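"""Virtual and pseudo proton positions for united-atom carbons.

United-atom force fields carry no aliphatic hydrogens, yet interproton
NOE distances need them.  Three construction rules cover the sialic-acid
carbons:

* CH (one missing proton, three heavy neighbors): the proton opposes the
  mean neighbor direction at 0.1 nm — no upper-bound correction;
* prochiral CH2 (two heavy neighbors): both tetrahedral completion
  positions plus their midpoint-averaged site; 0.09 nm is added to NOE
  upper bounds referencing the averaged site;
* CH3: a pseudo site on the carbon itself with a 0.1 nm bound correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import ConformerEnsemble
from .geometry import opposing_direction, tetrahedral_directions

CH_BOND = 0.100  # nm, virtual C-H length

UPPER_BOUND_CORRECTIONS = {"CH": 0.0, "CH2_prochiral": 0.09, "CH3": 0.1}


@dataclass(frozen=True)
class PseudoAtomSpec:
    united_carbon_class: str  # CH | CH2_prochiral | CH3

    def __post_init__(self) -> None:
        if self.united_carbon_class not in UPPER_BOUND_CORRECTIONS:
            raise ValueError(
                f"unknown united carbon class {self.united_carbon_class!r}"
            )

    @property
    def upper_bound_correction(self) -> float:
        """NOE upper-bound correction in nm for this pseudo-atom class."""
        return UPPER_BOUND_CORRECTIONS[self.united_carbon_class]


def virtual_ch_proton(carbon, neighbors) -> np.ndarray:
    """Virtual H of a united CH carbon with three heavy neighbors."""
    if len(neighbors) != 3:
        raise ValueError(f"CH construction needs 3 neighbors, got {len(neighbors)}")
    c = np.asarray(carbon, float)
    return c + CH_BOND * opposing_direction(c, neighbors)


def prochiral_ch2_protons(carbon, neighbor_a, neighbor_b) -> dict[str, np.ndarray]:
    """Virtual protons of a prochiral CH2 carbon.

    Returns {"R": ..., "S": ..., "avg": ...}.  The R/S assignment uses
    the handedness of the (neighbor_a, neighbor_b, H) triple — the proton
    on the positive side of the neighbor cross product is labelled R, so
    mirroring the frame swaps the two labels.  ``avg`` is the midpoint
    site used with the 0.09 nm upper-bound correction.
    """
    c = np.asarray(carbon, float)
    d1, d2 = tetrahedral_directions(c, neighbor_a, neighbor_b)
    h1 = c + CH_BOND * d1
    h2 = c + CH_BOND * d2
    a = np.asarray(neighbor_a, float) - c
    b = np.asarray(neighbor_b, float) - c
    normal = np.cross(a, b)
    if np.dot(h1 - c, normal) >= 0:
        r_h, s_h = h1, h2
    else:
        r_h, s_h = h2, h1
    return {"R": r_h, "S": s_h, "avg": 0.5 * (r_h + s_h)}


def pseudo_ch3_site(carbon) -> np.ndarray:
    """Pseudo atom of a united CH3: coincides with the carbon."""
    return np.asarray(carbon, float).copy()


def build_virtual_protons(ens: ConformerEnsemble, frame: int,
                          residue: int, carbon: str,
                          spec: PseudoAtomSpec) -> dict[str, np.ndarray]:
    """Virtual/pseudo proton site(s) of one united carbon in one frame.

    Keys: ``H<carbon digits>`` for CH; ``H..R``/``H..S``/``H..avg`` for
    prochiral CH2; ``H..pseudo`` for CH3.
    """
    ci = ens.index(residue, carbon)
    c = ens.coords[frame, ci]
    heavy = [j for j in ens.neighbors(ci) if ens.atoms[j].element != "H"]
    suffix = carbon[1:]
    kind = spec.united_carbon_class
    expected = {"CH": 3, "CH2_prochiral": 2, "CH3": 1}[kind]
    if len(heavy) != expected:
        raise ValueError(
            f"{kind} carbon {carbon} (residue {residue}) has {len(heavy)} "
            f"heavy neighbors; expected {expected}"
        )
    if kind == "CH":
        return {f"H{suffix}": virtual_ch_proton(c, [ens.coords[frame, j]
                                                    for j in heavy])}
    if kind == "CH2_prochiral":
        sites = prochiral_ch2_protons(c, ens.coords[frame, heavy[0]],
                                      ens.coords[frame, heavy[1]])
        return {f"H{suffix}R": sites["R"], f"H{suffix}S": sites["S"],
                f"H{suffix}avg": sites["avg"]}
    return {f"H{suffix}pseudo": pseudo_ch3_site(c)}
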