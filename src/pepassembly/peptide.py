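"""Peptide identity: sequence plus termini blocking state.

A :class:`PeptideSpec` is the chemical identity everything downstream derives
from — the ionizable-site inventory, the molecular mass, and the residue
sequence the coordinate builders and readers validate against.  "Uncapped"
means a free amine N-terminus and a free carboxyl C-terminus (H2N-...-OH);
end-capping (N-acetyl, C-amide) removes the corresponding ionizable group.
"""

from __future__ import annotations

from dataclasses import dataclass

#: One-letter codes of the 20 canonical amino acids.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# Average residue (monomer-minus-water) masses, g/mol, and the monoisotopic
# equivalents; free termini add one water.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MASS_AVERAGE = 18.0153
WATER_MASS_MONOISOTOPIC = 18.010565


class PeptideValidationError(ValueError):
    """Raised when a peptide sequence or termini specification is invalid."""


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence with its termini blocking state.

    Parameters
    ----------
    sequence
        One-letter amino-acid string, N to C.
    n_term_free
        True for a free amine N-terminus (ionizable); False for a blocked
        (e.g. acetylated) one.
    c_term_free
        True for a free carboxyl C-terminus (ionizable); False for a blocked
        (e.g. amidated) one.
    """

    sequence: str
    n_term_free: bool = True
    c_term_free: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideValidationError("peptide sequence must be non-empty")
        for pos, letter in enumerate(self.sequence, start=1):
            if letter not in AMINO_ACIDS:
                raise PeptideValidationError(
                    f"unknown residue letter {letter!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def molecular_weight(self, mode: str = "average") -> float:
        """Molecular mass in g/mol, summed from standard residue masses.

        Free termini (either one) add one water; a peptide capped at both
        ends is treated as the bare chain of residue masses, which matches
        the convention that capping groups replace the terminal H/OH.
        """
        if mode == "average":
            table, water = AVERAGE_RESIDUE_MASS, WATER_MASS_AVERAGE
        elif mode == "monoisotopic":
            table, water = MONOISOTOPIC_RESIDUE_MASS, WATER_MASS_MONOISOTOPIC
        else:
            raise ValueError(f"mode must be 'average' or 'monoisotopic', got {mode!r}")
        mass = sum(table[aa] for aa in self.sequence)
        if self.n_term_free or self.c_term_free:
            mass += water
        return mass


#: The heptapeptide studied throughout: H2N-AAAAAAK-OH.
A6K = PeptideSpec("AAAAAAK", n_term_free=True, c_term_free=True)
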