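"""Metropolis sampling of model torsional potentials.

This is the surrogate for the MD engine: a single-torsion-update
Metropolis chain whose stationary distribution is the Boltzmann weight of
(model potential + biasing potential).  One torsion is perturbed per
step, chosen cyclically; proposals are uniform within +/- step_size.
Seeds are explicit arguments — there is no global random state.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import _mc_core
from .potentials import CosineTerm, GaussianWellTerm, ModelTorsionPotential
from .trajectory import TorsionTrajectory
from .units import kt, wrap_angle


def encode_potential(potential: ModelTorsionPotential) -> tuple[np.ndarray, np.ndarray]:
    """Pack the potential terms into the flat tables the MC kernel reads."""
    index = {n: i for i, n in enumerate(potential.torsion_names)}
    n_terms = len(potential.terms)
    code = np.zeros((n_terms, 7))
    touch = np.zeros((n_terms, potential.n_torsions), dtype=np.bool_)
    for k, term in enumerate(potential.terms):
        if isinstance(term, CosineTerm):
            i0 = index[term.name]
            code[k] = [_mc_core.KIND_COSINE, i0, -1,
                       term.amplitude, term.multiplicity, term.phase, 0.0]
            touch[k, i0] = True
        elif isinstance(term, GaussianWellTerm):
            if len(term.names) == 1:
                i0 = index[term.names[0]]
                code[k] = [_mc_core.KIND_GAUSS1, i0, -1,
                           term.center[0], term.depth, term.width, 0.0]
                touch[k, i0] = True
            else:
                i0, i1 = (index[n] for n in term.names)
                code[k] = [_mc_core.KIND_GAUSS2, i0, i1, term.center[0],
                           term.center[1], term.depth, term.width]
                touch[k, i0] = True
                touch[k, i1] = True
        else:  # pragma: no cover - guarded by ModelTorsionPotential
            raise TypeError(f"cannot encode term of type {type(term)!r}")
    return code, touch


def _encode_biases(potential: ModelTorsionPotential, biases) -> tuple:
    """Pack a (possibly empty) list of LEBiasPotential into flat arrays."""
    from .leus import LEBiasPotential  # local import to avoid a cycle

    if biases is None:
        biases = []
    elif isinstance(biases, LEBiasPotential):
        biases = [biases]
    biases = list(biases)
    index = {n: i for i, n in enumerate(potential.torsion_names)}
    n = len(biases)
    b_i0 = np.full(n, -1, dtype=np.int64)
    b_i1 = np.full(n, -1, dtype=np.int64)
    b_ng = np.zeros(n, dtype=np.int64)
    b_sigma = np.zeros(n)
    b_cut = np.zeros(n, dtype=np.int64)
    chunks = []
    offsets = [0]
    for b, bias in enumerate(biases):
        names = bias.grid.torsion_names
        for nm in names:
            if nm not in index:
                raise ValueError(
                    f"bias torsion {nm!r} not found in potential torsions "
                    f"{potential.torsion_names}"
                )
        b_i0[b] = index[names[0]]
        if len(names) == 2:
            b_i1[b] = index[names[1]]
        b_ng[b] = bias.grid.ng
        b_sigma[b] = bias.grid.sigma
        b_cut[b] = bias.neighbor_cut
        chunks.append(bias.weights.ravel())
        offsets.append(offsets[-1] + bias.weights.size)
    wflat = np.concatenate(chunks) if chunks else np.zeros(0)
    b_off = np.asarray(offsets[:-1] + [offsets[-1]], dtype=np.int64)[:n + 1]
    return biases, b_i0, b_i1, b_ng, b_sigma, b_cut, wflat, b_off


def metropolis_sample(potential: ModelTorsionPotential, n_steps: int,
                      step_size: float = 30.0, seed: int = 0,
                      bias=None, save_stride: int = 1,
                      start: Sequence[float] | None = None,
                      _build_index: int = -1, _dep_stride: int = 1,
                      _c: float = 0.0) -> TorsionTrajectory:
    """Sample Boltzmann statistics of (potential + bias) by Metropolis MC.

    Frames are saved every ``save_stride`` steps; each saved frame records
    the total biasing energy acting on it (zero for unbiased runs), which
    is exactly what Boltzmann reweighting needs.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not (0.0 < step_size <= 180.0):
        raise ValueError("step_size must lie in (0, 180] degrees")
    if save_stride < 1 or save_stride > n_steps:
        raise ValueError("save_stride must lie in [1, n_steps]")
    code, touch = encode_potential(potential)
    bias_list, b_i0, b_i1, b_ng, b_sigma, b_cut, wflat, b_off = _encode_biases(
        potential, bias
    )
    if start is None:
        theta0 = np.zeros(potential.n_torsions)
    else:
        theta0 = wrap_angle(np.asarray(start, dtype=float)).astype(float)
        if theta0.shape != (potential.n_torsions,):
            raise ValueError("start must provide one angle per torsion")
    frames, bias_e, n_acc, n_dep = _mc_core.run_chain(
        theta0, code, touch, kt(potential.temperature), int(n_steps),
        float(step_size), int(save_stride), b_i0, b_i1, b_ng, b_sigma, b_cut,
        wflat, b_off, int(_build_index), int(_dep_stride), float(_c),
        int(seed),
    )
    if np.isnan(frames).any() or np.isnan(bias_e).any():
        raise FloatingPointError("NaN encountered during sampling")
    # propagate deposits back into the built bias object
    if _build_index >= 0:
        bias_obj = bias_list[_build_index]
        lo = int(b_off[_build_index])
        bias_obj.weights[...] = wflat[lo:lo + bias_obj.weights.size].reshape(
            bias_obj.weights.shape
        )
        bias_obj.n_depositions += int(n_dep)
    traj = TorsionTrajectory(potential.torsion_names, frames,
                             bias_energy=bias_e, step_stride=save_stride,
                             seed=seed)
    traj.acceptance_fraction = n_acc / n_steps
    return traj
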