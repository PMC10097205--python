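"""Residue property scales, grouped alphabets and physico-chemical constants.

Each :class:`PropertyScale` maps every one of the 20 canonical residues to a
real value.  The grouped alphabets used for composition–transition–
distribution (CTD) encoding follow the standard three-state property
groupings (hydrophobicity, polarity, polarizability, charge, solvent
accessibility, secondary-structure propensity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from lspsuite.sequence_io import CANONICAL_RESIDUES


@dataclass(frozen=True)
class PropertyScale:
    """A named map from each canonical residue to a real value."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(CANONICAL_RESIDUES):
            raise ValueError(
                f"scale {self.name!r} must key exactly the 20 canonical residues; "
                f"missing={sorted(set(CANONICAL_RESIDUES) - keys)} "
                f"extra={sorted(keys - set(CANONICAL_RESIDUES))}"
            )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


#: Kyte–Doolittle hydropathy; the scale underlying GRAVY.
KYTE_DOOLITTLE = PropertyScale(
    "kyte_doolittle",
    {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
)

#: Average residue masses (Da) for chain-linked residues; add one water for
#: the free peptide.  Standard average isotopic masses.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

#: EMBOSS pKa set (as used by the EMBOSS ``iep`` tool).
EMBOSS_PKA = {
    "n_term": 8.6,
    "c_term": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

# Three-state property groupings for CTD encoding.  Keys are alphabet names,
# values are the three residue groups in a fixed order.
CTD_ALPHABETS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
}


def group_map(alphabet: tuple[str, ...]) -> dict[str, int]:
    """Residue → group-index map for a grouped alphabet; must cover all 20."""
    mapping: dict[str, int] = {}
    for index, group in enumerate(alphabet):
        for residue in group:
            if residue in mapping:
                raise ValueError(f"residue {residue} assigned to two groups")
            mapping[residue] = index
    missing = set(CANONICAL_RESIDUES) - set(mapping)
    if missing:
        raise ValueError(f"alphabet does not cover residues {sorted(missing)}")
    return mapping
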