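"""Karplus-type back-calculation of vicinal 3J(H,H) coupling constants.

Two relations are implemented:

* the Haasnoot (electronegativity-corrected Karplus) equation for
  3J(H6,H7) and 3J(H7,H8),

      3J = P1 cos^2(t) + P2 cos(t) + P3
           + sum_i Dchi_i * [P4 + P5 cos^2(s_i t + P6 |Dchi_i|)],

  where the sum runs over the four non-hydrogen substituents of the
  H-C-C-H fragment, s_i = +/-1 encodes the substituent orientation and
  the group electronegativity carries a beta-substituent correction
  Dchi_i = Dchi_alpha - P7 * sum(Dchi_beta);

* a DFT-parameterized trigonometric relation for the prochiral pair
  3J(H8,H9R) / 3J(H8,H9S) as a function of omega9 (the S line is
  evaluated at omega9 - 120 degrees).

Electronegativity differences are Huggins-type values relative to H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Haasnoot parameters P1..P7 for four-substituent H-C-C-H fragments.
HAASNOOT_P = (13.7, -0.73, 0.0, 0.56, -2.47, 16.9, 0.14)

#: Huggins electronegativity differences relative to hydrogen.
DEFAULT_ELECTRONEGATIVITIES = {"H": 0.0, "C": 0.4, "N": 0.85, "O": 1.3}

#: cosine/sine coefficients (a0, c1, s1, c2, s2) of the DFT relations.
DFT_R_COEFFS = (5.08, 0.47, 0.90, -0.12, 4.86)
DFT_S_COEFFS = (4.92, -1.29, 0.05, 4.58, 0.07)
DFT_S_SHIFT = -120.0  # the S relation is evaluated at omega9 - 120 deg


@dataclass(frozen=True)
class Substituent:
    """One non-hydrogen substituent of a vicinal H-C-C-H fragment."""

    element: str
    sign: int  # +1 "positive", -1 "negative" orientation
    beta_elements: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("substituent sign must be +1 or -1")


@dataclass(frozen=True)
class SubstituentPattern:
    """The four substituents flanking a vicinal proton pair."""

    substituents: tuple[Substituent, Substituent, Substituent, Substituent]

    def __post_init__(self) -> None:
        if len(self.substituents) != 4:
            raise ValueError("a vicinal H-C-C-H pair has four substituents")


@dataclass(frozen=True)
class KarplusParameterSet:
    haasnoot_P: tuple[float, ...] = HAASNOOT_P
    electronegativities: dict = field(
        default_factory=lambda: dict(DEFAULT_ELECTRONEGATIVITIES))
    dft_R: tuple[float, ...] = DFT_R_COEFFS
    dft_S: tuple[float, ...] = DFT_S_COEFFS
    dft_S_shift: float = DFT_S_SHIFT

    def __post_init__(self) -> None:
        if len(self.haasnoot_P) != 7:
            raise ValueError("exactly seven Haasnoot parameters required")

    def delta_chi(self, sub: Substituent) -> float:
        """Group electronegativity with the beta-substituent correction."""
        try:
            alpha = self.electronegativities[sub.element]
            beta = sum(self.electronegativities[e] for e in sub.beta_elements)
        except KeyError as exc:
            raise KeyError(
                f"no electronegativity entry for element class {exc}"
            ) from None
        return alpha - self.haasnoot_P[6] * beta


DEFAULT_PARAMS = KarplusParameterSet()

# Substituent patterns of the sialic-acid glycerol arm.  The orientation
# signs pair the two substituents on each carbon with opposite parity,
# as the Newman geometry requires; the assignment reproduces the
# low/high coupling extremes of the gauche/anti rotamers.
H7H8_PATTERN = SubstituentPattern((
    Substituent("O", -1, ()),          # O7 (beta H)
    Substituent("C", +1, ("O", "C")),  # C6 (beta O6, C5)
    Substituent("O", -1, ()),          # O8 (beta H; free chain end)
    Substituent("C", +1, ("O",)),      # C9 (beta O9)
))

#: variant with O8 glycosylated (beta substituent C instead of H)
H7H8_PATTERN_GLYCOSYLATED = SubstituentPattern((
    Substituent("O", -1, ()),
    Substituent("C", +1, ("O", "C")),
    Substituent("O", -1, ("C",)),
    Substituent("C", +1, ("O",)),
))

H6H7_PATTERN = SubstituentPattern((
    Substituent("O", -1, ("C",)),      # ring O6 (beta C2)
    Substituent("C", +1, ("N", "C")),  # C5 (beta N5, C4)
    Substituent("O", -1, ()),          # O7
    Substituent("C", +1, ("O",)),      # C8 (beta O8)
))


def haasnoot_J(theta: float, pattern: SubstituentPattern = H7H8_PATTERN,
               params: KarplusParameterSet = DEFAULT_PARAMS) -> float:
    """Haasnoot coupling (Hz) for proton-proton torsion theta (degrees)."""
    p1, p2, p3, p4, p5, p6, _ = params.haasnoot_P
    t = math.radians(theta)
    j = p1 * math.cos(t) ** 2 + p2 * math.cos(t) + p3
    for sub in pattern.substituents:
        dchi = params.delta_chi(sub)
        arg = math.radians(sub.sign * theta + p6 * abs(dchi))
        j += dchi * (p4 + p5 * math.cos(arg) ** 2)
    return j


def haasnoot_J_array(theta, pattern: SubstituentPattern = H7H8_PATTERN,
                     params: KarplusParameterSet = DEFAULT_PARAMS) -> np.ndarray:
    """Vectorized :func:`haasnoot_J`."""
    p1, p2, p3, p4, p5, p6, _ = params.haasnoot_P
    theta = np.asarray(theta, dtype=float)
    t = np.radians(theta)
    j = p1 * np.cos(t) ** 2 + p2 * np.cos(t) + p3
    for sub in pattern.substituents:
        dchi = params.delta_chi(sub)
        arg = np.radians(sub.sign * theta + p6 * abs(dchi))
        j = j + dchi * (p4 + p5 * np.cos(arg) ** 2)
    return j


def dft_karplus_J(omega9, proton: str,
                  params: KarplusParameterSet = DEFAULT_PARAMS):
    """DFT Karplus coupling (Hz) of H8 to the pro-R or pro-S H9 proton."""
    if proton == "R":
        a0, c1, s1, c2, s2 = params.dft_R
        w = np.radians(np.asarray(omega9, dtype=float))
    elif proton == "S":
        a0, c1, s1, c2, s2 = params.dft_S
        w = np.radians(np.asarray(omega9, dtype=float) + params.dft_S_shift)
    else:
        raise ValueError(f"proton must be 'R' or 'S', got {proton!r}")
    j = (a0 + c1 * np.cos(w) + s1 * np.sin(w)
         + c2 * np.cos(2 * w) + s2 * np.sin(2 * w))
    return float(j) if j.shape == () else j


# ---------------------------------------------------------------------------
# Ensemble averages
# ---------------------------------------------------------------------------

#: heavy-atom torsion governing each coupling
COUPLING_TORSION = {"JH6H7": "omega7", "JH7H8": "omega8",
                    "JH8H9R": "omega9", "JH8H9S": "omega9"}

#: proton-proton torsion offset relative to the heavy-atom torsion; with
#: the +120/-120 tetrahedral proton placements on either carbon the two
#: shifts cancel, but the offset stays configurable per stereochemistry.
DEFAULT_THETA_OFFSETS = {"JH6H7": 0.0, "JH7H8": 0.0}

COUPLING_PATTERNS = {"JH6H7": H6H7_PATTERN, "JH7H8": H7H8_PATTERN}


def couplings_per_frame(obj, coupling: str, residue: int | None = None,
                        theta_offset: float | None = None,
                        pattern: SubstituentPattern | None = None,
                        params: KarplusParameterSet = DEFAULT_PARAMS) -> np.ndarray:
    """Per-frame J values (Hz) from a torsion trajectory or a Cartesian
    ensemble.

    For a trajectory, proton torsions are derived from the heavy-atom
    torsion by the (configurable) tetrahedral offset; for an ensemble the
    proton torsion is measured from the explicit proton coordinates.
    """
    from .ensemble import ConformerEnsemble
    from .geometry import measure_torsion
    from .trajectory import TorsionTrajectory

    if coupling not in COUPLING_TORSION:
        raise KeyError(f"unknown coupling label {coupling!r}; "
                       f"choose from {sorted(COUPLING_TORSION)}")
    if isinstance(obj, TorsionTrajectory):
        torsion = obj.angles(COUPLING_TORSION[coupling])
        if coupling in ("JH8H9R", "JH8H9S"):
            return np.asarray(dft_karplus_J(torsion, coupling[-1], params))
        offset = (DEFAULT_THETA_OFFSETS[coupling]
                  if theta_offset is None else theta_offset)
        pat = pattern or COUPLING_PATTERNS[coupling]
        return haasnoot_J_array(torsion + offset, pat, params)
    if isinstance(obj, ConformerEnsemble):
        if residue is None:
            raise ValueError("residue index required for ensemble input")
        quads = {"JH6H7": ("H6", "C6", "C7", "H7"),
                 "JH7H8": ("H7", "C7", "C8", "H8"),
                 "JH8H9R": ("O9", "C9", "C8", "O8"),
                 "JH8H9S": ("O9", "C9", "C8", "O8")}[coupling]
        thetas = np.array([
            measure_torsion(*(obj.position(f, residue, n) for n in quads))
            for f in range(obj.n_frames)
        ])
        if coupling in ("JH8H9R", "JH8H9S"):
            return np.asarray(dft_karplus_J(thetas, coupling[-1], params))
        pat = pattern or COUPLING_PATTERNS[coupling]
        return haasnoot_J_array(thetas, pat, params)
    raise TypeError(f"unsupported input type {type(obj)!r}")


def ensemble_J(obj, coupling: str, weights=None, residue: int | None = None,
               theta_offset: float | None = None,
               pattern: SubstituentPattern | None = None,
               params: KarplusParameterSet = DEFAULT_PARAMS) -> tuple[float, float]:
    """Ensemble-averaged coupling: linear average of per-frame J,
    optionally reweighted (LEUS unbiasing weights), with block error."""
    from .leus import block_weighted_mean

    j = couplings_per_frame(obj, coupling, residue, theta_offset, pattern,
                            params)
    if weights is None:
        weights = np.ones_like(j)
    return block_weighted_mean(j, np.asarray(weights, dtype=float))
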