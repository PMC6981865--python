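"""Model torsional potentials emulating the dimer free-energy landscapes.

These closed-form potentials stand in for the solvated force-field surface
of a sialic-acid dimer: the (phi, psi) glycosidic surface carries three
minima (the A/B/C states), the side-chain surface confines omega7 near
+60 degrees (g+) and leaves omega8 bimodal near 60/180 degrees.  All
potentials are sums of terms that each depend on one or two torsions, are
360-degree periodic, and are finite everywhere, so exact Boltzmann
statistics are available from grid quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .units import KB, DEFAULT_TEMPERATURE, wrap_angle, wrap_angle_scalar

_DEG2RAD = math.pi / 180.0


@dataclass(frozen=True)
class CosineTerm:
    """U(x) = amplitude * (1 - cos(m*(x - phase))) / 2, in kJ/mol."""

    name: str
    amplitude: float
    multiplicity: int = 1
    phase: float = 0.0

    @property
    def names(self) -> tuple[str, ...]:
        return (self.name,)

    def value_scalar(self, x: float) -> float:
        return 0.5 * self.amplitude * (
            1.0 - math.cos(self.multiplicity * (x - self.phase) * _DEG2RAD)
        )

    def value(self, x):
        return 0.5 * self.amplitude * (
            1.0 - np.cos(np.deg2rad(self.multiplicity * (np.asarray(x) - self.phase)))
        )


@dataclass(frozen=True)
class GaussianWellTerm:
    """Periodic Gaussian well of given depth (kJ/mol) and width (degrees).

    One- or two-dimensional; the distance to the center is the wrapped
    (minimal-image) angular difference, which keeps the term periodic.
    """

    names_: tuple[str, ...]
    center: tuple[float, ...]
    depth: float
    width: float = 25.0

    @property
    def names(self) -> tuple[str, ...]:
        return self.names_

    def value_scalar(self, *angles: float) -> float:
        d2 = 0.0
        for a, c in zip(angles, self.center):
            d = wrap_angle_scalar(a - c)
            d2 += d * d
        return -self.depth * math.exp(-d2 / (2.0 * self.width * self.width))

    def value(self, *angles):
        d2 = 0.0
        for a, c in zip(angles, self.center):
            d = wrap_angle(np.asarray(a) - c)
            d2 = d2 + d * d
        return -self.depth * np.exp(-d2 / (2.0 * self.width * self.width))


Term = CosineTerm | GaussianWellTerm


@dataclass
class ModelTorsionPotential:
    """Sum of periodic terms over named torsions.

    ``terms_for(i)`` gives the terms touching torsion i together with the
    positions of their arguments, which lets a single-torsion Monte Carlo
    move evaluate only the affected energy contributions.
    """

    torsion_names: tuple[str, ...]
    terms: tuple[Term, ...]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.torsion_names = tuple(self.torsion_names)
        self.terms = tuple(self.terms)
        index = {n: i for i, n in enumerate(self.torsion_names)}
        for t in self.terms:
            for n in t.names:
                if n not in index:
                    raise ValueError(
                        f"term references unknown torsion {n!r}; "
                        f"potential has {self.torsion_names}"
                    )
        self._term_args = [tuple(index[n] for n in t.names) for t in self.terms]
        self._by_torsion: list[list[int]] = [[] for _ in self.torsion_names]
        for k, args in enumerate(self._term_args):
            for i in args:
                self._by_torsion[i].append(k)

    @property
    def n_torsions(self) -> int:
        return len(self.torsion_names)

    def energy_scalar(self, angles: Sequence[float]) -> float:
        e = 0.0
        for t, args in zip(self.terms, self._term_args):
            e += t.value_scalar(*(angles[i] for i in args))
        if math.isnan(e):
            raise FloatingPointError("potential energy evaluated to NaN")
        return e

    def partial_energy_scalar(self, angles: Sequence[float], torsion_index: int) -> float:
        """Sum of only the terms that involve the given torsion."""
        e = 0.0
        for k in self._by_torsion[torsion_index]:
            t = self.terms[k]
            e += t.value_scalar(*(angles[i] for i in self._term_args[k]))
        return e

    def energy(self, angles) -> np.ndarray:
        """Vectorized energy.

        ``angles`` is either a mapping name -> array or an array of shape
        (..., n_torsions) ordered like ``torsion_names``.
        """
        if isinstance(angles, Mapping):
            cols = [np.asarray(angles[n], dtype=float) for n in self.torsion_names]
        else:
            arr = np.asarray(angles, dtype=float)
            cols = [arr[..., i] for i in range(self.n_torsions)]
        e = np.zeros(np.broadcast(*cols).shape) if cols else np.zeros(())
        for t, args in zip(self.terms, self._term_args):
            e = e + t.value(*(cols[i] for i in args))
        return e

    # -- exact statistics on <=2D blocks -------------------------------

    def _separable_block(self, names: Sequence[str]) -> None:
        """Raise unless the requested torsions form a separable block."""
        wanted = set(names)
        for t in self.terms:
            tset = set(t.names)
            if tset & wanted and not tset <= wanted:
                raise ValueError(
                    f"torsions {names} are coupled to {tset - wanted} and do "
                    "not form a separable block"
                )

    def grid_energy(self, names: Sequence[str], resolution: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Energy of the separable block on a regular grid.

        Returns (grid_axes_stack, energy): for 1D, axes shape (n,), energy
        (n,); for 2D, energy (n, n) with axes indexing (names[0], names[1]).
        """
        self._separable_block(names)
        n = int(round(360.0 / resolution))
        axis = -180.0 + resolution * np.arange(n)
        if len(names) == 1:
            cols = {names[0]: axis}
            e = np.zeros(n)
        elif len(names) == 2:
            g0, g1 = np.meshgrid(axis, axis, indexing="ij")
            cols = {names[0]: g0, names[1]: g1}
            e = np.zeros((n, n))
        else:
            raise ValueError("grid quadrature supports one or two torsions")
        for t, _ in zip(self.terms, self._term_args):
            if set(t.names) <= set(names):
                e = e + t.value(*(cols[nm] for nm in t.names))
        return axis, e

    def boltzmann_probability(self, names: Sequence[str], temperature: float | None = None,
                              resolution: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Exact Boltzmann probability of a separable block by quadrature."""
        T = self.temperature if temperature is None else temperature
        axis, e = self.grid_energy(names, resolution)
        w = np.exp(-(e - e.min()) / (KB * T))
        return axis, w / w.sum()


def find_minima(potential: ModelTorsionPotential, names: Sequence[str],
                resolution: float = 1.0) -> list[tuple[tuple[float, ...], float]]:
    """Locate local minima of a <=2D separable block by periodic grid scan.

    A grid point is a minimum when strictly below all its (wrapped)
    neighbors.  Returns [(angles, energy), ...] sorted by energy.
    """
    axis, e = potential.grid_energy(names, resolution)
    out: list[tuple[tuple[float, ...], float]] = []
    if e.ndim == 1:
        lower = (e < np.roll(e, 1)) & (e < np.roll(e, -1))
        for i in np.nonzero(lower)[0]:
            out.append(((float(axis[i]),), float(e[i])))
    else:
        is_min = np.ones_like(e, dtype=bool)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                is_min &= e < np.roll(np.roll(e, di, axis=0), dj, axis=1)
        for i, j in zip(*np.nonzero(is_min)):
            out.append(((float(axis[i]), float(axis[j])), float(e[i, j])))
    return sorted(out, key=lambda t: t[1])


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESETS = ("flat", "double_well_1d", "dimer1_like", "dimer2_like")


def _dimer_terms(phi_a: float, depths_abc: tuple[float, float, float],
                 omega8_depths: tuple[float, float]) -> tuple[Term, ...]:
    """Shared construction of a dimer-like 4-torsion surface.

    Three (phi, psi) wells (states A, B, C) plus a g+-confined omega7 and a
    bimodal omega8.  Well depths control the relative free energies of the
    states; equal widths keep entropic contributions comparable.
    """
    da, db, dc = depths_abc
    d60, d180 = omega8_depths
    return (
        GaussianWellTerm(("phi", "psi"), (phi_a, 120.0), da, 25.0),
        GaussianWellTerm(("phi", "psi"), (-60.0, -120.0), db, 25.0),
        GaussianWellTerm(("phi", "psi"), (160.0, -60.0), dc, 25.0),
        GaussianWellTerm(("omega7",), (60.0,), 20.0, 20.0),
        GaussianWellTerm(("omega8",), (60.0,), d60, 30.0),
        GaussianWellTerm(("omega8",), (180.0,), d180, 30.0),
    )


def build_model_potential(preset: str, temperature: float = DEFAULT_TEMPERATURE,
                          **params) -> ModelTorsionPotential:
    """Construct a named model potential.

    Presets
    -------
    ``flat``
        Identically zero energy; single torsion (``torsion`` keyword, default
        ``phi``).
    ``double_well_1d``
        One torsion with two minima 180 degrees apart:
        U = barrier*(1-cos(2(x-m1)))/2 + delta*(1-cos(x-m1))/2, minima at
        ``minimum1`` (energy 0) and ``minimum1 + 180`` (energy ``delta``);
        keywords ``barrier`` (default 25 kJ/mol), ``delta`` (default 3),
        ``minimum1`` (default 60), ``torsion`` (default ``phi``).
    ``dimer1_like`` / ``dimer2_like``
        Four torsions (phi, psi, omega7, omega8): three (phi, psi) wells
        (A, B, C), omega7 confined near +60, omega8 bimodal near 60/180.
        In the dimer1-like surface state A sits at phi = 60 and omega8
        favors 60; the dimer2-like variant shifts A to phi = 30, makes C
        the global (phi, psi) state and favors omega8 = 180.
    """
    if preset == "flat":
        name = params.pop("torsion", "phi")
        _reject_extra(params, preset)
        return ModelTorsionPotential((name,), (), temperature)
    if preset == "double_well_1d":
        barrier = params.pop("barrier", 25.0)
        delta = params.pop("delta", 3.0)
        m1 = params.pop("minimum1", 60.0)
        name = params.pop("torsion", "phi")
        _reject_extra(params, preset)
        terms = (
            CosineTerm(name, amplitude=barrier, multiplicity=2, phase=m1),
            CosineTerm(name, amplitude=delta, multiplicity=1, phase=m1),
        )
        return ModelTorsionPotential((name,), terms, temperature)
    if preset == "dimer1_like":
        _reject_extra(params, preset)
        terms = _dimer_terms(60.0, (30.0, 6.7, 16.3), (12.0, 8.0))
    elif preset == "dimer2_like":
        _reject_extra(params, preset)
        terms = _dimer_terms(30.0, (23.4, 17.9, 30.0), (8.0, 12.0))
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    return ModelTorsionPotential(
        ("phi", "psi", "omega7", "omega8"), terms, temperature
    )


def _reject_extra(params: dict, preset: str) -> None:
    if params:
        raise TypeError(f"unknown parameters for preset {preset!r}: {sorted(params)}")
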