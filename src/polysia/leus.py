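"""Local elevation umbrella sampling: bias build-up, frozen-bias sampling,
exact reweighting and free-energy map construction.

The two-phase scheme: during the build (LE) phase a penalty of ``c``
kJ/mol is deposited at the currently occupied bin of a 1D or 2D torsion
grid at a fixed stride, progressively flattening the sampled surface.
The accumulated bias is then frozen and used as an umbrella (US phase);
unbiased statistics are recovered exactly by weighting each saved frame
with exp(+U_bias/kBT):

    P(Q) = < delta(Q - Q_i) exp(U_bias,i/kBT) > / < exp(U_bias,i/kBT) >

and free energies follow as G(Q) = -kBT ln P(Q), shifted so the visited
minimum is zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .potentials import ModelTorsionPotential
from .sampling import metropolis_sample
from .trajectory import TorsionTrajectory
from .units import kt, wrap_angle

DEFAULT_NG = 36
DEFAULT_C = 0.005  # kJ/mol per deposition


@dataclass(frozen=True)
class LEGridSpec:
    """Grid over one or two torsions: Ng bins per dimension, Gaussian
    deposit width sigma (default 360/Ng degrees) and force-constant
    increment c (kJ/mol)."""

    torsion_names: tuple[str, ...]
    ng: int = DEFAULT_NG
    sigma: float | None = None
    c: float = DEFAULT_C

    def __post_init__(self) -> None:
        object.__setattr__(self, "torsion_names", tuple(self.torsion_names))
        if len(self.torsion_names) not in (1, 2):
            raise ValueError("LE grids cover one or two torsions")
        if self.ng < 4:
            raise ValueError("ng must be >= 4")
        if self.sigma is None:
            object.__setattr__(self, "sigma", 360.0 / self.ng)
        if self.sigma <= 0 or self.c <= 0:
            raise ValueError("sigma and c must be positive")

    @property
    def ndim(self) -> int:
        return len(self.torsion_names)

    @property
    def bin_width(self) -> float:
        return 360.0 / self.ng

    @property
    def bin_centers(self) -> np.ndarray:
        return -180.0 + 360.0 * (np.arange(self.ng) + 0.5) / self.ng

    def bin_index(self, angles) -> tuple[np.ndarray, ...]:
        """Half-open bin assignment [center-w/2, center+w/2) per dimension."""
        angles = np.atleast_2d(np.asarray(angles, dtype=float))
        idx = []
        for d in range(self.ndim):
            k = np.floor((wrap_angle(angles[..., d]) + 180.0) / self.bin_width)
            idx.append(k.astype(int) % self.ng)
        return tuple(idx)


class LEBiasPotential:
    """Accumulated local-elevation bias: per-bin weights (kJ/mol) spread
    by periodic Gaussians of width sigma.

    Once frozen the weights are immutable — sampling against an unfrozen
    bias is refused by :func:`us_sample` so the build can never silently
    continue during production.
    """

    #: evaluation cutoff in units of sigma (contributions beyond are dropped)
    CUTOFF_SIGMAS = 4.0

    def __init__(self, grid: LEGridSpec, weights: np.ndarray | None = None,
                 frozen: bool = False, n_depositions: int = 0) -> None:
        self.grid = grid
        shape = (grid.ng,) * grid.ndim
        if weights is None:
            weights = np.zeros(shape)
        else:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != shape:
                raise ValueError(f"weights must have shape {shape}")
            if (weights < 0).any():
                raise ValueError("bias weights must be non-negative")
        self.weights = weights
        self.frozen = bool(frozen)
        self.n_depositions = int(n_depositions)
        if self.frozen:
            self.weights.setflags(write=False)

    @property
    def neighbor_cut(self) -> int:
        """Evaluation truncation radius in bins (>= CUTOFF_SIGMAS * sigma)."""
        return min(self.grid.ng // 2,
                   int(math.ceil(self.CUTOFF_SIGMAS * self.grid.sigma
                                 / self.grid.bin_width)))

    def freeze(self) -> "LEBiasPotential":
        self.frozen = True
        self.weights.setflags(write=False)
        return self

    def total_deposited(self) -> float:
        return float(self.weights.sum())

    def energy(self, angles) -> np.ndarray:
        """Bias energy (kJ/mol) at angle(s); vectorized.

        ``angles``: array of shape (..., ndim) or a scalar/1-vector for 1D.
        Uses the same truncated-Gaussian rule as the sampling kernel, so
        recorded per-frame bias energies are exactly reproducible.
        """
        g = self.grid
        arr = np.asarray(angles, dtype=float)
        if g.ndim == 1 and arr.ndim <= 1 and arr.shape in ((), (1,)):
            arr = arr.reshape(1, 1)
        arr = np.atleast_2d(arr)
        if arr.shape[-1] != g.ndim:
            raise ValueError(f"expected angles with last axis {g.ndim}")
        centers = g.bin_centers
        inv2s2 = 1.0 / (2.0 * g.sigma ** 2)
        cut = self.neighbor_cut
        idx = g.bin_index(arr)
        out = np.zeros(arr.shape[:-1])
        offsets = np.arange(-cut, cut + 1)
        if g.ndim == 1:
            x = wrap_angle(arr[..., 0])
            ks = (idx[0][..., None] + offsets) % g.ng
            d = wrap_angle(x[..., None] - centers[ks])
            out = (self.weights[ks] * np.exp(-d * d * inv2s2)).sum(axis=-1)
        else:
            x = wrap_angle(arr[..., 0])
            y = wrap_angle(arr[..., 1])
            k0 = (idx[0][..., None] + offsets) % g.ng
            k1 = (idx[1][..., None] + offsets) % g.ng
            dx = wrap_angle(x[..., None] - centers[k0])
            dy = wrap_angle(y[..., None] - centers[k1])
            ex = np.exp(-dx * dx * inv2s2)
            ey = np.exp(-dy * dy * inv2s2)
            w = self.weights[k0[..., :, None], k1[..., None, :]]
            out = np.einsum("...ij,...i,...j->...", w, ex, ey)
        return out if out.shape else float(out)

    # -- serialization --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "torsion_names": list(self.grid.torsion_names),
            "ng": self.grid.ng,
            "sigma": self.grid.sigma,
            "c": self.grid.c,
            "frozen": self.frozen,
            "n_depositions": self.n_depositions,
            "weights": self.weights.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "LEBiasPotential":
        payload = json.loads(Path(path).read_text())
        grid = LEGridSpec(tuple(payload["torsion_names"]), payload["ng"],
                          payload["sigma"], payload["c"])
        return cls(grid, np.asarray(payload["weights"]),
                   frozen=payload["frozen"],
                   n_depositions=payload["n_depositions"])


def le_build(potential: ModelTorsionPotential, grid: LEGridSpec,
             n_steps: int, deposition_stride: int = 1, seed: int = 0,
             step_size: float = 30.0,
             start=None) -> LEBiasPotential:
    """Local-elevation build phase: Metropolis sampling with progressive
    deposition of c kJ/mol at the currently occupied bin.

    Returns the (unfrozen) accumulated bias; total deposited energy equals
    c times the number of depositions.
    """
    for name in grid.torsion_names:
        if name not in potential.torsion_names:
            raise ValueError(f"grid torsion {name!r} not in potential")
    if n_steps == 0:
        return LEBiasPotential(grid)
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if deposition_stride < 1 or deposition_stride > n_steps:
        raise ValueError("deposition_stride must lie in [1, n_steps]")
    bias = LEBiasPotential(grid)
    metropolis_sample(potential, n_steps, step_size=step_size, seed=seed,
                      bias=[bias], save_stride=n_steps, start=start,
                      _build_index=0, _dep_stride=deposition_stride,
                      _c=grid.c)
    return bias


def us_sample(potential: ModelTorsionPotential, bias, n_steps: int,
              save_stride: int = 1, seed: int = 0, step_size: float = 30.0,
              start=None) -> TorsionTrajectory:
    """Umbrella-sampling phase under one or more frozen biases.

    Saved frames carry the total bias energy (sum over all applied grids)
    so that reweighting can undo the umbrella exactly.
    """
    biases = [bias] if isinstance(bias, LEBiasPotential) else list(bias)
    for b in biases:
        if not b.frozen:
            raise ValueError(
                "us_sample requires frozen biases; call .freeze() after the "
                "build phase"
            )
    return metropolis_sample(potential, n_steps, step_size=step_size,
                             seed=seed, bias=biases,
                             save_stride=save_stride, start=start)


# ---------------------------------------------------------------------------
# Reweighting
# ---------------------------------------------------------------------------

def reweight_weights(traj: TorsionTrajectory, temperature: float) -> np.ndarray:
    """Per-frame unbiasing weights exp(U_bias/kBT), max-shifted so the
    largest weight is one (overflow-safe; the shift cancels in all
    ratios)."""
    u = traj.bias_energy / kt(temperature)
    w = np.exp(u - u.max())
    if not np.isfinite(w).all() or w.sum() == 0:
        raise ValueError("invalid reweighting weights")
    return w


def block_weighted_mean(values: np.ndarray, weights: np.ndarray,
                        n_blocks: int = 10) -> tuple[float, float]:
    """Weighted mean with a block-averaging error estimate.

    The frame sequence is cut into ``n_blocks`` contiguous blocks; the
    standard error of the per-block weighted means (weighted by block
    weight mass) estimates the statistical error including serial
    correlation on scales shorter than a block.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.isnan(values).any():
        raise ValueError("NaN in observable values")
    total_w = weights.sum()
    if total_w <= 0:
        raise ValueError("all reweighting weights are zero")
    mean = float(np.sum(weights * values) / total_w)
    n = len(values)
    n_blocks = min(n_blocks, n)
    if n_blocks < 2:
        return mean, float("nan")
    bounds = np.linspace(0, n, n_blocks + 1, dtype=int)
    means, masses = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        wm = weights[a:b].sum()
        if wm > 0:
            means.append(np.sum(weights[a:b] * values[a:b]) / wm)
            masses.append(wm)
    means = np.asarray(means)
    masses = np.asarray(masses) / np.sum(masses)
    nb = len(means)
    if nb < 2:
        return mean, float("nan")
    var = np.sum(masses * (means - mean) ** 2) / (nb - 1)
    return mean, float(np.sqrt(var))


def reweight_observable(traj: TorsionTrajectory, observable_values,
                        temperature: float) -> tuple[float, float]:
    """Unbiased ensemble mean of a per-frame observable with statistical
    error (block averaging over 10 blocks)."""
    obs = np.asarray(observable_values, dtype=float)
    if obs.shape != (traj.n_frames,):
        raise ValueError("observable length must equal frame count")
    w = reweight_weights(traj, temperature)
    return block_weighted_mean(obs, w)


# ---------------------------------------------------------------------------
# Free-energy maps
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyMap:
    """Reweighted free-energy surface on a torsion grid.

    ``g`` holds NaN on never-visited bins (additionally available as
    ``mask``); the visited minimum is exactly zero.
    """

    torsion_names: tuple[str, ...]
    bin_centers: np.ndarray
    g: np.ndarray
    mask: np.ndarray  # True where the bin was never visited
    temperature: float

    @property
    def ndim(self) -> int:
        return len(self.torsion_names)

    def value_at(self, angles, unvisited_penalty: float = 25.0) -> np.ndarray:
        """Periodic (bi)linear interpolation of G at arbitrary angles.

        Unvisited bins enter the interpolation at (max visited G +
        ``unvisited_penalty``) so that geometry enumeration can rank
        against them without producing NaN.
        """
        filled = self.g.copy()
        fill = np.nanmax(self.g) + unvisited_penalty if self.mask.any() else 0.0
        filled[self.mask] = fill
        arr = np.atleast_2d(np.asarray(angles, dtype=float))
        ng = len(self.bin_centers)
        width = 360.0 / ng
        out = np.zeros(arr.shape[0])
        # fractional index relative to bin centers
        fs = []
        for d in range(self.ndim):
            f = (wrap_angle(arr[:, d]) - self.bin_centers[0]) / width
            fs.append(f)
        if self.ndim == 1:
            f = fs[0]
            i0 = np.floor(f).astype(int) % ng
            t = f - np.floor(f)
            out = filled[i0] * (1 - t) + filled[(i0 + 1) % ng] * t
        else:
            f0, f1 = fs
            i0 = np.floor(f0).astype(int) % ng
            j0 = np.floor(f1).astype(int) % ng
            t0 = f0 - np.floor(f0)
            t1 = f1 - np.floor(f1)
            i1 = (i0 + 1) % ng
            j1 = (j0 + 1) % ng
            out = (filled[i0, j0] * (1 - t0) * (1 - t1)
                   + filled[i1, j0] * t0 * (1 - t1)
                   + filled[i0, j1] * (1 - t0) * t1
                   + filled[i1, j1] * t0 * t1)
        return out if out.size > 1 else float(out[0])

    def to_csv(self, path: str | Path) -> None:
        if self.ndim == 1:
            df = pd.DataFrame({self.torsion_names[0]: self.bin_centers,
                               "G": self.g, "visited": ~self.mask})
        else:
            g0, g1 = np.meshgrid(self.bin_centers, self.bin_centers,
                                 indexing="ij")
            df = pd.DataFrame({self.torsion_names[0]: g0.ravel(),
                               self.torsion_names[1]: g1.ravel(),
                               "G": self.g.ravel(),
                               "visited": ~self.mask.ravel()})
        df.to_csv(path, index=False, float_format="%.6g")

    def plot(self, path: str | Path, contour_interval: float = 5.0) -> None:
        """Contour plot with unvisited regions rendered dark."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        if self.ndim == 1:
            ax.plot(self.bin_centers, self.g, "o-")
            ax.set_xlabel(self.torsion_names[0] + " (deg)")
            ax.set_ylabel("G (kJ/mol)")
        else:
            gm = np.ma.masked_array(self.g, self.mask)
            top = float(np.nanmax(self.g)) if np.isfinite(self.g).any() else 1.0
            levels = np.arange(0.0, top + contour_interval, contour_interval)
            cmap = plt.get_cmap("viridis").copy()
            cmap.set_bad("#00004d")
            pcm = ax.pcolormesh(self.bin_centers, self.bin_centers, gm.T,
                                cmap=cmap, shading="nearest")
            if len(levels) > 1:
                ax.contour(self.bin_centers, self.bin_centers, gm.T,
                           levels=levels, colors="white", linewidths=0.6)
            fig.colorbar(pcm, ax=ax, label="G (kJ/mol)")
            ax.set_xlabel(self.torsion_names[0] + " (deg)")
            ax.set_ylabel(self.torsion_names[1] + " (deg)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def free_energy_map(traj: TorsionTrajectory, grid: LEGridSpec,
                    temperature: float) -> FreeEnergyMap:
    """Reweighted histogram -> G = -kBT ln P, minimum shifted to zero.

    Bins with zero raw counts are masked out rather than assigned a
    number (they were never visited, so the data say nothing about them).
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    for name in grid.torsion_names:
        if name not in traj.torsion_names:
            raise ValueError(f"trajectory lacks torsion {name!r}")
    cols = np.column_stack([traj.angles(n) for n in grid.torsion_names])
    w = reweight_weights(traj, temperature)
    idx = grid.bin_index(cols)
    shape = (grid.ng,) * grid.ndim
    counts = np.zeros(shape)
    mass = np.zeros(shape)
    np.add.at(counts, idx, 1.0)
    np.add.at(mass, idx, w)
    p = mass / mass.sum()
    mask = counts == 0
    g = np.full(shape, np.nan)
    visited = ~mask
    g[visited] = -kt(temperature) * np.log(p[visited])
    g[visited] -= np.nanmin(g[visited])
    return FreeEnergyMap(grid.torsion_names, grid.bin_centers, g, mask,
                         temperature)
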