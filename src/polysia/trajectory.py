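"""Torsion-angle time series — the surrogate for an MD trajectory.

A :class:`TorsionTrajectory` stores named periodic torsion angles for a
sequence of saved frames together with the biasing energy that acted on
each frame (zero for unbiased runs).  It is the object every downstream
analysis (reweighting, free-energy maps, J-coupling averages) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .units import wrap_angle

#: Torsion names used along the 2->8 glycosidic linkage.
TORSION_NAMES = ("phi", "psi", "omega7", "omega8", "omega9")

BIAS_COLUMN = "bias_energy"


@dataclass(frozen=True)
class TorsionDefinition:
    """A named torsion defined by four atom labels.

    The glycosidic and side-chain torsions follow the standard
    definitions for the alpha-(2->8) linkage:
    phi = O6-C2-O8'-C8', psi = C2-O8'-C8'-C7', omega7 = O7-C7-C6-O6,
    omega8 = O8-C8-C7-O7, omega9 = O9-C9-C8-O8.
    """

    name: str
    atom_quadruple: tuple[str, str, str, str]
    period: float = 360.0

    def __post_init__(self) -> None:
        if len(self.atom_quadruple) != 4:
            raise ValueError("a torsion needs exactly four atom labels")
        if len(set(self.atom_quadruple)) != 4:
            raise ValueError(
                f"torsion {self.name}: atom labels must be distinct, "
                f"got {self.atom_quadruple}"
            )


#: Standard linkage torsion definitions (primed labels = preceding residue).
STANDARD_TORSIONS = {
    "phi": TorsionDefinition("phi", ("O6", "C2", "O8'", "C8'")),
    "psi": TorsionDefinition("psi", ("C2", "O8'", "C8'", "C7'")),
    "omega7": TorsionDefinition("omega7", ("O7", "C7", "C6", "O6")),
    "omega8": TorsionDefinition("omega8", ("O8", "C8", "C7", "O7")),
    "omega9": TorsionDefinition("omega9", ("O9", "C9", "C8", "O8")),
}


@dataclass
class TorsionTrajectory:
    """Time series of torsion angles (degrees) with per-frame bias energy."""

    torsion_names: tuple[str, ...]
    frames: np.ndarray  # (n_frames, n_torsions), degrees in [-180, 180)
    bias_energy: np.ndarray | None = None  # kJ/mol per frame
    step_stride: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frames.shape[0] == 0:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != len(self.torsion_names):
            raise ValueError(
                f"frame width {self.frames.shape[1]} does not match "
                f"{len(self.torsion_names)} torsion names"
            )
        self.frames = wrap_angle(self.frames)
        if self.bias_energy is None:
            self.bias_energy = np.zeros(self.frames.shape[0])
        else:
            self.bias_energy = np.asarray(self.bias_energy, dtype=float)
            if self.bias_energy.shape != (self.frames.shape[0],):
                raise ValueError("bias_energy length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def angles(self, name: str) -> np.ndarray:
        """Time series of one named torsion."""
        try:
            idx = self.torsion_names.index(name)
        except ValueError:
            raise KeyError(
                f"torsion {name!r} not in trajectory {self.torsion_names}"
            ) from None
        return self.frames[:, idx]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.frames, columns=list(self.torsion_names))
        df[BIAS_COLUMN] = self.bias_energy
        df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TorsionTrajectory":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != BIAS_COLUMN]
        bias = df[BIAS_COLUMN].to_numpy() if BIAS_COLUMN in df.columns else None
        return cls(tuple(cols), df[cols].to_numpy(), bias_energy=bias)


def concatenate(trajectories: Sequence[TorsionTrajectory]) -> TorsionTrajectory:
    """Join trajectories sharing the same torsion names."""
    names = trajectories[0].torsion_names
    for t in trajectories[1:]:
        if t.torsion_names != names:
            raise ValueError("trajectories have mismatched torsion names")
    return TorsionTrajectory(
        names,
        np.concatenate([t.frames for t in trajectories]),
        bias_energy=np.concatenate([t.bias_energy for t in trajectories]),
    )
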