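"""In-memory coordinate model: atoms, residues, chains, multi-frame systems.

This is the uniform container every analysis module works on, whether the
coordinates came from a PDB/GRO file or from the synthetic conformer
generator.  Coordinates are stored in Å; box edges (when present) follow
the simulation convention of nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .peptide import PeptideSpec

__all__ = ["Atom", "Residue", "Conformation", "PeptideSystem", "BACKBONE_ATOMS"]

#: Atom names a residue must carry to be usable by dihedral/turn analysis.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Average atomic masses (u) for the elements the model places.
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

_ELEMENT_FROM_NAME = {
    "N": "N", "H": "H", "CA": "C", "CB": "C", "C": "C", "O": "O",
    "OXT": "O", "NZ": "N",
}


def element_for(name: str) -> str:
    """Element symbol for an atom name (first alphabetic character heuristic
    for names outside the backbone/side-chain set this package places)."""
    if name in _ELEMENT_FROM_NAME:
        return _ELEMENT_FROM_NAME[name]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element for atom name {name!r}")


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be finite 3-vectors")


@dataclass
class Residue:
    index: int  # 1-based within chain
    letter: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords_of(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coords

    @property
    def usable(self) -> bool:
        """True when all analysis-grade backbone atoms (N, CA, C, O) exist."""
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_ATOMS)


@dataclass
class Conformation:
    """One chain's coordinates, with the peptide identity they must match."""

    chain_id: str
    residues: list[Residue]
    peptide: PeptideSpec

    def __post_init__(self) -> None:
        seq = "".join(r.letter for r in self.residues)
        if seq != self.peptide.sequence:
            raise ValueError(
                f"chain {self.chain_id}: residue letters {seq!r} do not match "
                f"peptide sequence {self.peptide.sequence!r}"
            )
        for want, res in enumerate(self.residues, start=1):
            if res.index != want:
                raise ValueError(
                    f"chain {self.chain_id}: residue indices must run 1..n "
                    f"consecutively (found {res.index} at position {want})"
                )
        for res in self.residues:
            if not res.usable:
                warnings.warn(
                    f"chain {self.chain_id} residue {res.index} lacks backbone "
                    "atoms; flagged unusable for dihedral/turn analysis",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.residues)

    def atom_coords(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        """Stacked coordinates of all atoms (optionally restricted by name)."""
        rows = [
            a.coords
            for r in self.residues
            for a in r.atoms
            if names is None or a.name in names
        ]
        return np.array(rows).reshape(-1, 3)

    def heavy_atom_coords(self) -> np.ndarray:
        rows = [a.coords for r in self.residues for a in r.atoms if a.element != "H"]
        return np.array(rows).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        """A rigidly moved copy: x -> R x + t."""
        out = Conformation(
            chain_id=self.chain_id,
            residues=[
                Residue(
                    r.index,
                    r.letter,
                    [Atom(a.name, a.element, rotation @ a.coords + translation) for a in r.atoms],
                )
                for r in self.residues
            ],
            peptide=self.peptide,
        )
        return out


@dataclass
class PeptideSystem:
    """Frames of multi-chain coordinates, the stand-in for MD snapshots.

    ``frames`` is a list of frames, each a list of :class:`Conformation`;
    ``box_nm`` holds orthorhombic edge lengths in nm when known.
    """

    frames: list[list[Conformation]]
    box_nm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.box_nm is not None:
            if any(e <= 0 for e in self.box_nm):
                raise ValueError("box edges must be positive")
        if self.frames:
            composition = [c.chain_id for c in self.frames[0]]
            for i, frame in enumerate(self.frames):
                if [c.chain_id for c in frame] != composition:
                    raise ValueError(
                        f"frame {i} chain composition differs from frame 0"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_chains(self) -> int:
        return len(self.frames[0]) if self.frames else 0
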