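"""Cartesian conformer ensembles for sialic-acid-like fragments.

Atoms follow the united-atom convention of carbohydrate force fields:
aliphatic CH/CH2/CH3 carbons may carry no explicit hydrogen (virtual
positions are constructed on demand), while hydroxyl, amide and the
side-chain protons needed for J-coupling analysis are explicit.
Coordinates are stored in nm; PDB files are written/read in Angstrom via
biotite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

NM_PER_ANGSTROM = 0.1

#: residue labels in chain order; "a" is the reducing end.
RESIDUE_LABELS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class Atom:
    name: str
    residue_index: int  # 1-based; residue 1 = label "a" = reducing end
    element: str
    united: bool = False

    @property
    def residue_label(self) -> str:
        return RESIDUE_LABELS[self.residue_index - 1]


def element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


class ConformerEnsemble:
    """Frames of labelled Cartesian coordinates with a shared topology."""

    def __init__(self, atoms: list[Atom], coords: np.ndarray,
                 bonds: list[tuple[int, int]] | None = None) -> None:
        self.atoms = list(atoms)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.shape[1:] != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        self.coords = coords
        self.bonds = sorted(tuple(sorted(b)) for b in (bonds or []))
        self._index = {(a.residue_index, a.name): i
                       for i, a in enumerate(self.atoms)}
        if len(self._index) != len(self.atoms):
            raise ValueError("duplicate (residue, atom name) pairs")
        self._neighbors: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for i, j in self.bonds:
            self._neighbors[i].append(j)
            self._neighbors[j].append(i)

    # -- bookkeeping ----------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return max(a.residue_index for a in self.atoms)

    def index(self, residue_index: int, name: str) -> int:
        try:
            return self._index[(residue_index, name)]
        except KeyError:
            raise KeyError(
                f"no atom {name!r} in residue {residue_index}"
            ) from None

    def has_atom(self, residue_index: int, name: str) -> bool:
        return (residue_index, name) in self._index

    def position(self, frame: int, residue_index: int, name: str) -> np.ndarray:
        return self.coords[frame, self.index(residue_index, name)]

    def neighbors(self, atom_index: int) -> list[int]:
        return self._neighbors[atom_index]

    def bonded(self, i: int, j: int) -> bool:
        return tuple(sorted((i, j))) in set(self.bonds)

    def add_frames(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        self.coords = np.concatenate([self.coords, coords])

    def clashes(self, frame: int, cutoff: float = 0.08) -> list[tuple[int, int]]:
        """Non-bonded atom pairs closer than ``cutoff`` nm (flagging, not
        fatal — mirrors the non-clashing selection of start structures).

        Pairs separated by one or two bonds are exempt.
        """
        xyz = self.coords[frame]
        d = np.linalg.norm(xyz[:, None] - xyz[None], axis=-1)
        exempt = set(self.bonds)
        for i, j in self.bonds:
            for k in self._neighbors[j]:
                if k != i:
                    exempt.add(tuple(sorted((i, k))))
            for k in self._neighbors[i]:
                if k != j:
                    exempt.add(tuple(sorted((j, k))))
        out = []
        ii, jj = np.nonzero(d < cutoff)
        for i, j in zip(ii, jj):
            if i < j and (i, j) not in exempt:
                out.append((int(i), int(j)))
        return out

    # -- PDB round trip -------------------------------------------------

    def to_pdb(self, path: str | Path) -> None:
        n = self.n_atoms
        arrays = []
        for f in range(self.n_frames):
            arr = struc.AtomArray(n)
            arr.coord = self.coords[f] / NM_PER_ANGSTROM
            arr.res_id = np.array([a.residue_index for a in self.atoms])
            arr.res_name = np.array(["SIA"] * n)
            arr.atom_name = np.array([a.name for a in self.atoms])
            arr.element = np.array([a.element for a in self.atoms])
            arr.hetero = np.array([True] * n)
            arrays.append(arr)
        stack = struc.stack(arrays)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))

    @classmethod
    def from_pdb(cls, path: str | Path) -> "ConformerEnsemble":
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        first = stack[0]
        atoms = []
        for i in range(first.array_length()):
            name = str(first.atom_name[i])
            el = str(first.element[i]) or element_from_name(name)
            atoms.append(Atom(name, int(first.res_id[i]), el))
        coords = stack.coord * NM_PER_ANGSTROM
        ens = cls(atoms, coords)
        ens.bonds = infer_bonds(ens)
        ens._neighbors = {i: [] for i in range(len(atoms))}
        for i, j in ens.bonds:
            ens._neighbors[i].append(j)
            ens._neighbors[j].append(i)
        return ens


def infer_bonds(ens: ConformerEnsemble, frame: int = 0,
                cutoff: float = 0.17) -> list[tuple[int, int]]:
    """Distance-based bond inference (H-H pairs excluded); covers the
    idealized bond lengths used by the fragment builder (0.10-0.153 nm)."""
    xyz = ens.coords[frame]
    d = np.linalg.norm(xyz[:, None] - xyz[None], axis=-1)
    bonds = []
    for i in range(ens.n_atoms):
        for j in range(i + 1, ens.n_atoms):
            if ens.atoms[i].element == "H" and ens.atoms[j].element == "H":
                continue
            if 0.05 < d[i, j] < cutoff:
                bonds.append((i, j))
    return bonds
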