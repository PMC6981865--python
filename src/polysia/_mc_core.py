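"""Numba-compiled Metropolis kernels shared by all torsional samplers.

The model potential is encoded as a flat float64 table (one row per term)
and the local-elevation biases as flat weight arrays, so the whole chain
runs in machine code.  The bias is a sum of periodic Gaussians centered
at bin centers; evaluation is truncated beyond ``cut`` bins from the
current position (relative error < exp(-8) of a single deposit at the
default 4-sigma cutoff).
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEG = np.pi / 180.0

# term kinds in the encoded potential table
KIND_COSINE = 0.0
KIND_GAUSS1 = 1.0
KIND_GAUSS2 = 2.0


@njit(cache=True)
def _wrap(x):
    return (x + 180.0) % 360.0 - 180.0


@njit(cache=True)
def _term_value(row, theta):
    kind = int(row[0])
    i0 = int(row[1])
    if kind == 0:
        # amplitude row[3], multiplicity row[4], phase row[5]
        return 0.5 * row[3] * (1.0 - np.cos(row[4] * (theta[i0] - row[5]) * DEG))
    elif kind == 1:
        # center row[3], depth row[4], width row[5]
        d = _wrap(theta[i0] - row[3])
        return -row[4] * np.exp(-(d * d) / (2.0 * row[5] * row[5]))
    else:
        # centers row[3], row[4], depth row[5], width row[6]
        i1 = int(row[2])
        d0 = _wrap(theta[i0] - row[3])
        d1 = _wrap(theta[i1] - row[4])
        return -row[5] * np.exp(-(d0 * d0 + d1 * d1) / (2.0 * row[6] * row[6]))


@njit(cache=True)
def _partial_energy(code, touch, theta, j):
    e = 0.0
    for k in range(code.shape[0]):
        if touch[k, j]:
            e += _term_value(code[k], theta)
    return e


@njit(cache=True)
def _total_energy(code, theta):
    e = 0.0
    for k in range(code.shape[0]):
        e += _term_value(code[k], theta)
    return e


@njit(cache=True)
def _bias_energy(b, theta, b_i0, b_i1, b_ng, b_sigma, b_cut, wflat, b_off):
    ng = b_ng[b]
    sig = b_sigma[b]
    off = b_off[b]
    cut = b_cut[b]
    binw = 360.0 / ng
    inv2s2 = 1.0 / (2.0 * sig * sig)
    x = theta[b_i0[b]]
    kx = int((x + 180.0) // binw) % ng
    e = 0.0
    if b_i1[b] < 0:
        for dk in range(-cut, cut + 1):
            k = (kx + dk) % ng
            w = wflat[off + k]
            if w != 0.0:
                d = _wrap(x - (-180.0 + binw * (k + 0.5)))
                e += w * np.exp(-d * d * inv2s2)
    else:
        y = theta[b_i1[b]]
        ky = int((y + 180.0) // binw) % ng
        for dkx in range(-cut, cut + 1):
            k0 = (kx + dkx) % ng
            dx = _wrap(x - (-180.0 + binw * (k0 + 0.5)))
            ex = np.exp(-dx * dx * inv2s2)
            row = off + k0 * ng
            for dky in range(-cut, cut + 1):
                k1 = (ky + dky) % ng
                w = wflat[row + k1]
                if w != 0.0:
                    dy = _wrap(y - (-180.0 + binw * (k1 + 0.5)))
                    e += w * ex * np.exp(-dy * dy * inv2s2)
    return e


@njit(cache=True)
def _total_bias(theta, b_i0, b_i1, b_ng, b_sigma, b_cut, wflat, b_off):
    e = 0.0
    for b in range(b_i0.shape[0]):
        e += _bias_energy(b, theta, b_i0, b_i1, b_ng, b_sigma, b_cut, wflat, b_off)
    return e


@njit(cache=True)
def run_chain(theta0, code, touch, kt, n_steps, step_size, save_stride,
              b_i0, b_i1, b_ng, b_sigma, b_cut, wflat, b_off,
              build_index, dep_stride, c_inc, seed):
    """Single-torsion-update Metropolis chain.

    Torsions are perturbed cyclically; ``build_index >= 0`` switches on
    local-elevation deposition into that bias every ``dep_stride`` steps.
    Returns (frames, bias_per_frame, n_accepted, n_deposited); the weight
    array of the built bias is updated in place.
    """
    np.random.seed(seed)
    n_t = theta0.shape[0]
    n_bias = b_i0.shape[0]
    theta = theta0.copy()
    n_save = n_steps // save_stride
    frames = np.empty((n_save, n_t))
    bias_out = np.zeros(n_save)
    n_acc = 0
    n_dep = 0
    isave = 0
    for step in range(n_steps):
        j = step % n_t
        old = theta[j]
        e_old = _partial_energy(code, touch, theta, j)
        for b in range(n_bias):
            if b_i0[b] == j or b_i1[b] == j:
                e_old += _bias_energy(b, theta, b_i0, b_i1, b_ng, b_sigma,
                                      b_cut, wflat, b_off)
        theta[j] = _wrap(old + (np.random.random() * 2.0 - 1.0) * step_size)
        e_new = _partial_energy(code, touch, theta, j)
        for b in range(n_bias):
            if b_i0[b] == j or b_i1[b] == j:
                e_new += _bias_energy(b, theta, b_i0, b_i1, b_ng, b_sigma,
                                      b_cut, wflat, b_off)
        de = e_new - e_old
        if de <= 0.0 or np.random.random() < np.exp(-de / kt):
            n_acc += 1
        else:
            theta[j] = old
        if build_index >= 0 and (step + 1) % dep_stride == 0:
            ng = b_ng[build_index]
            binw = 360.0 / ng
            kx = int((theta[b_i0[build_index]] + 180.0) // binw) % ng
            if b_i1[build_index] < 0:
                wflat[b_off[build_index] + kx] += c_inc
            else:
                ky = int((theta[b_i1[build_index]] + 180.0) // binw) % ng
                wflat[b_off[build_index] + kx * ng + ky] += c_inc
            n_dep += 1
        if (step + 1) % save_stride == 0:
            for t in range(n_t):
                frames[isave, t] = theta[t]
            bias_out[isave] = _total_bias(theta, b_i0, b_i1, b_ng, b_sigma,
                                          b_cut, wflat, b_off)
            isave += 1
    return frames, bias_out, n_acc, n_dep


@njit(cache=True)
def run_chain_1d(x0, lo, hi, kt, n_steps, step_size, save_stride, lam,
                 sys_kind, sys_params, seed):
    """Metropolis chain for the 1D lambda-coupled toy systems used in TI.

    ``sys_kind`` selects the closed-form Hamiltonian implemented in
    :func:`_system_energy`; the coordinate lives on [lo, hi] (rejecting
    out-of-range proposals, i.e. hard walls) unless the system is
    periodic (kind >= 100), in which case it wraps.
    """
    np.random.seed(seed)
    x = x0
    n_save = n_steps // save_stride
    xs = np.empty(n_save)
    e_cur = _system_energy(x, lam, sys_kind, sys_params)
    isave = 0
    n_acc = 0
    for step in range(n_steps):
        prop = x + (np.random.random() * 2.0 - 1.0) * step_size
        ok = True
        if sys_kind >= 100:
            prop = _wrap(prop)
        elif prop < lo or prop > hi:
            ok = False
        if ok:
            e_new = _system_energy(prop, lam, sys_kind, sys_params)
            de = e_new - e_cur
            if de <= 0.0 or np.random.random() < np.exp(-de / kt):
                x = prop
                e_cur = e_new
                n_acc += 1
        if (step + 1) % save_stride == 0:
            xs[isave] = x
            isave += 1
    return xs, x, n_acc


@njit(cache=True)
def _system_energy(x, lam, kind, p):
    # kind 0: box + switched harmonic spring: lam * 0.5*k*(x-x0)^2
    if kind == 0:
        d = x - p[1]
        return lam * 0.5 * p[0] * d * d
    # kind 1: base harmonic + soft-bond restraint on the same coordinate
    #   p = [k_base, x_base, kA, kB, r0A, r0B, alpha]
    if kind == 1:
        d = x - p[1]
        e = 0.5 * p[0] * d * d
        return e + _soft_bond(x, lam, p[2], p[3], p[4], p[5], p[6])
    # kind 100: periodic double-well torsion + lam-scaled dihedral restraint
    #   p = [barrier, delta, m1, k_r, target]
    if kind == 100:
        e = 0.5 * p[0] * (1.0 - np.cos(2.0 * (x - p[2]) * DEG))
        e += 0.5 * p[1] * (1.0 - np.cos((x - p[2]) * DEG))
        d = _wrap(x - p[4])
        return e + lam * 0.5 * p[3] * d * d
    return 0.0


@njit(cache=True)
def _soft_bond(r, lam, ka, kb, r0a, r0b, alpha):
    sa = 1.0 + alpha * lam * (r - r0a) ** 2
    sb = 1.0 + alpha * (1.0 - lam) * (r - r0b) ** 2
    d = r - ((1.0 - lam) * r0a + lam * r0b)
    return 0.5 * ((1.0 - lam) * ka / sa + lam * kb / sb) * d * d
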