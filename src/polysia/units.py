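"""Package-wide unit conventions and angle helpers.

Units are fixed everywhere: energies in kJ/mol, distances in nm, angles in
degrees, temperatures in K.  Angles live on the half-open interval
[-180, 180) and every arithmetic operation re-wraps onto it.
"""

from __future__ import annotations

import math

import numpy as np

#: Boltzmann constant in kJ mol^-1 K^-1.
KB = 0.008314463

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 300.0


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


def wrap_angle(angle):
    """Wrap angle(s) in degrees onto [-180, 180).

    Works on scalars and arrays alike.
    """
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


def wrap_angle_scalar(angle: float) -> float:
    """Scalar fast path of :func:`wrap_angle` (used in sampler inner loops)."""
    return (angle + 180.0) % 360.0 - 180.0


def angle_difference(a, b):
    """Minimal-image difference a - b, wrapped onto [-180, 180)."""
    return wrap_angle(np.asarray(a) - np.asarray(b))


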