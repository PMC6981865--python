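"""Free-energy differences by thermodynamic integration (TI) and one-step
(Zwanzig) perturbation (OSP), with cycle-closure checking.

TI integrates the ensemble average of dH/dlambda over a lambda schedule,

    dG(A->B) = int_0^1 < dH/dlambda >_lambda dlambda,

sampling each lambda point sequentially, each chain starting from the
final configuration of the previous point.  OSP removes a restraint from
an ensemble B in a single exponential average,

    dG(B->C) = -kBT ln < exp(+U_res/kBT) >_B,

computed with log-sum-exp; the estimate degrades when the restraint
energies exceed ~10 kBT anywhere in the sampled ensemble, which is
flagged as poor overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import _mc_core
from .units import kt

#: default 12-point schedule, denser near the endpoints where the
#: integrand of a switched-on restraint varies fastest
DEFAULT_LAMBDAS = (0.0, 0.025, 0.05, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9,
                   0.95, 1.0)


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered lambda points 0 -> 1 with per-point chain lengths.

    ``reverse=True`` traverses the same points 1 -> 0 (the integral then
    measures G(0) - G(1)), used for forward/reverse consistency checks.
    """

    lambda_points: tuple[float, ...] = DEFAULT_LAMBDAS
    n_equil: int = 5_000
    n_prod: int = 50_000
    seed: int = 0
    reverse: bool = False

    def __post_init__(self) -> None:
        lp = self.lambda_points
        if lp[0] != 0.0 or lp[-1] != 1.0:
            raise ValueError("schedule must start at 0 and end at 1")
        if any(b <= a for a, b in zip(lp, lp[1:])):
            raise ValueError("lambda points must be strictly increasing")


class LambdaSystem1D:
    """A 1D coordinate with a closed-form lambda-coupled Hamiltonian,
    sampled by the compiled Metropolis kernel.

    Concrete systems are built by the factory classmethods; ``kind``
    selects the Hamiltonian implemented in the sampling kernel, and
    dH/dlambda is supplied as a Python callable (vectorized).
    """

    def __init__(self, kind: int, params, lo: float, hi: float,
                 dhdl, energy, x0: float, step_size: float,
                 periodic: bool = False) -> None:
        self.kind = kind
        self.params = np.asarray(params, dtype=float)
        self.lo, self.hi = lo, hi
        self.dhdl = dhdl
        self.energy = energy
        self.x0 = x0
        self.step_size = step_size
        self.periodic = periodic

    @classmethod
    def harmonic_switch(cls, k: float, x0: float, lo: float, hi: float,
                        step_size: float = 0.1) -> "LambdaSystem1D":
        """Particle in a box [lo, hi] with a switched-on spring
        H(lam) = lam * 1/2 k (x - x0)^2."""
        params = [k, x0]
        return cls(0, params, lo, hi,
                   dhdl=lambda x, lam: 0.5 * k * (np.asarray(x) - x0) ** 2,
                   energy=lambda x, lam: lam * 0.5 * k * (np.asarray(x) - x0) ** 2,
                   x0=0.5 * (lo + hi), step_size=step_size)

    @classmethod
    def soft_bond_on_harmonic(cls, k_base: float, x_base: float,
                              sb, lo: float, hi: float,
                              step_size: float = 0.02) -> "LambdaSystem1D":
        """Harmonic base potential plus a soft-bond restraint on the same
        coordinate (a 1D cartoon of restraining an interatomic distance)."""
        from .restraints import soft_bond_dHdlambda, soft_bond_energy

        params = [k_base, x_base, sb.k_a, sb.k_b, sb.r0_a, sb.r0_b, sb.alpha]

        def dhdl(x, lam):
            return np.array([soft_bond_dHdlambda(float(xi), lam, sb)
                             for xi in np.atleast_1d(x)])

        def energy(x, lam):
            base = 0.5 * k_base * (np.asarray(x) - x_base) ** 2
            res = np.array([soft_bond_energy(float(xi), lam, sb)
                            for xi in np.atleast_1d(x)])
            return base + res

        return cls(1, params, lo, hi, dhdl, energy, x0=x_base,
                   step_size=step_size)

    @classmethod
    def restrained_double_well(cls, barrier: float, delta: float, m1: float,
                               k_r: float, target: float,
                               step_size: float = 30.0) -> "LambdaSystem1D":
        """Periodic double-well torsion with a lambda-scaled harmonic
        dihedral restraint (k_r in kJ mol^-1 degree^-2)."""
        params = [barrier, delta, m1, k_r, target]

        def wrap(a):
            return (np.asarray(a) + 180.0) % 360.0 - 180.0

        def dhdl(x, lam):
            return 0.5 * k_r * wrap(np.asarray(x) - target) ** 2

        def energy(x, lam):
            xr = np.radians(np.asarray(x, dtype=float))
            e = 0.5 * barrier * (1 - np.cos(2 * np.radians(np.asarray(x) - m1)))
            e = e + 0.5 * delta * (1 - np.cos(np.radians(np.asarray(x) - m1)))
            return e + lam * 0.5 * k_r * wrap(np.asarray(x) - target) ** 2

        return cls(100, params, -180.0, 180.0, dhdl, energy, x0=m1,
                   step_size=step_size, periodic=True)

    def sample(self, lam: float, n_steps: int, x_start: float, seed: int,
               save_stride: int = 1):
        xs, x_final, _ = _mc_core.run_chain_1d(
            float(x_start), self.lo, self.hi, self._kt, int(n_steps),
            float(self.step_size), int(save_stride), float(lam),
            self.kind, self.params, int(seed))
        return xs, x_final

    # temperature is injected by ti_run before sampling
    _kt: float = 2.494338


def _block_error(values: np.ndarray, n_blocks: int = 10) -> float:
    n = len(values)
    if n < n_blocks:
        return float("nan")
    bounds = np.linspace(0, n, n_blocks + 1, dtype=int)
    means = np.array([values[a:b].mean() for a, b in zip(bounds[:-1],
                                                         bounds[1:])])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


@dataclass
class TIResult:
    lambdas: np.ndarray
    dhdl_means: np.ndarray
    dhdl_errors: np.ndarray
    delta_g: float
    delta_g_error: float
    integration_rule: str = "trapezoid"

    def to_dict(self) -> dict:
        return {"lambdas": self.lambdas.tolist(),
                "dhdl_means": self.dhdl_means.tolist(),
                "dhdl_errors": self.dhdl_errors.tolist(),
                "delta_g": self.delta_g,
                "delta_g_error": self.delta_g_error,
                "integration_rule": self.integration_rule}


def ti_run(system: LambdaSystem1D, schedule: LambdaSchedule,
           temperature: float) -> TIResult:
    """Thermodynamic integration along the schedule.

    Chains are warmed sequentially: the start configuration at each
    lambda is the final configuration of the previous one.  dG is the
    trapezoid over per-lambda means; its error combines per-lambda block
    errors with the trapezoid weights in quadrature.
    """
    system._kt = kt(temperature)
    lambdas = np.asarray(schedule.lambda_points)
    order = lambdas[::-1] if schedule.reverse else lambdas
    means = {}
    errors = {}
    x = system.x0
    for i, lam in enumerate(order):
        seed = (schedule.seed * 1009 + i * 7919 + 13) % (2 ** 31)
        if schedule.n_equil:
            _, x = system.sample(lam, schedule.n_equil, x, seed)
        xs, x = system.sample(lam, schedule.n_prod, x, seed + 1)
        dh = np.asarray(system.dhdl(xs, lam), dtype=float)
        if not np.isfinite(dh).all():
            raise FloatingPointError(f"non-finite dH/dlambda at lambda={lam}")
        means[lam] = float(dh.mean())
        errors[lam] = _block_error(dh)
    m = np.array([means[l] for l in lambdas])
    e = np.array([errors[l] for l in lambdas])
    dg = float(np.trapezoid(m, lambdas))
    w = np.zeros_like(lambdas)
    w[0] = (lambdas[1] - lambdas[0]) / 2
    w[-1] = (lambdas[-1] - lambdas[-2]) / 2
    w[1:-1] = (lambdas[2:] - lambdas[:-2]) / 2
    dg_err = float(np.sqrt(np.nansum((w * e) ** 2)))
    if schedule.reverse:
        dg = -dg  # reversed traversal measures G(0) - G(1)
    return TIResult(lambdas, m, e, dg, dg_err)


@dataclass
class OSPResult:
    delta_g: float
    delta_g_error: float
    effective_sample_size: float
    max_ures_over_kt: float
    poor_overlap: bool

    def to_dict(self) -> dict:
        return {"delta_g": self.delta_g,
                "delta_g_error": self.delta_g_error,
                "effective_sample_size": self.effective_sample_size,
                "max_ures_over_kt": self.max_ures_over_kt,
                "poor_overlap": self.poor_overlap}


def osp_run(u_res, temperature: float, overlap_warn: float = 10.0) -> OSPResult:
    """Free energy of removing a restraint from the ensemble sampled with
    it: dG = -kBT ln < exp(+U_res/kBT) >.

    ``u_res``: per-frame restraint energies (kJ/mol) of the restrained
    ensemble.  Uses log-sum-exp throughout; the error is a 10-block
    estimate; a warning is issued when max |U_res|/kBT exceeds
    ``overlap_warn``.
    """
    u = np.asarray(u_res, dtype=float)
    if u.size == 0:
        raise ValueError("empty ensemble")
    if not np.isfinite(u).all():
        raise ValueError("non-finite restraint energies")
    kbt = kt(temperature)
    z = u / kbt
    n = u.size
    dg = -kbt * (logsumexp(z) - np.log(n))
    w = np.exp(z - z.max())
    ess = float(w.sum() ** 2 / np.sum(w ** 2))
    max_ratio = float(np.abs(z).max())
    poor = max_ratio > overlap_warn
    if poor:
        warnings.warn(
            f"one-step perturbation overlap is poor: max |U_res|/kBT = "
            f"{max_ratio:.1f} > {overlap_warn}", RuntimeWarning)
    n_blocks = min(10, n)
    if n_blocks >= 2:
        bounds = np.linspace(0, n, n_blocks + 1, dtype=int)
        bg = np.array([
            -kbt * (logsumexp(z[a:b]) - np.log(b - a))
            for a, b in zip(bounds[:-1], bounds[1:])
        ])
        err = float(bg.std(ddof=1) / np.sqrt(n_blocks))
    else:
        err = float("nan")
    return OSPResult(float(dg), err, ess, max_ratio, poor)


@dataclass
class CycleReport:
    ti_delta_g: float
    osp_delta_g: float
    direct_delta_g: float
    combined_error: float

    @property
    def composed(self) -> float:
        return self.ti_delta_g + self.osp_delta_g

    @property
    def closure(self) -> float:
        """Composed A->B->C minus the direct A->C reference."""
        return self.composed - self.direct_delta_g

    def closes(self, n_sigma: float = 3.0) -> bool:
        return abs(self.closure) <= n_sigma * self.combined_error

    def to_dict(self) -> dict:
        return {"ti_delta_g": self.ti_delta_g,
                "osp_delta_g": self.osp_delta_g,
                "composed": self.composed,
                "direct_delta_g": self.direct_delta_g,
                "closure": self.closure,
                "combined_error": self.combined_error}


def cycle_check(ti: TIResult, osp: OSPResult,
                direct_delta_g: float,
                direct_error: float = 0.0) -> CycleReport:
    """Compose dG(A->B) (TI) with dG(B->C) (OSP) and compare against a
    direct A->C reference with combined statistical error."""
    err = float(np.sqrt(np.nansum(np.array([
        ti.delta_g_error, osp.delta_g_error, direct_error]) ** 2)))
    return CycleReport(ti.delta_g, osp.delta_g, direct_delta_g, err)
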