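"""Amino-acid alphabets and physicochemical property tables.

The fixed residue order used for all matrix output is the conventional
biochemical ordering A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO, Union

#: Canonical ordering of the 20 standard residues (rows of substitution matrices).
AA_ORDER: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

STANDARD_AA: frozenset[str] = frozenset(AA_ORDER)

#: Row index of each residue in the canonical ordering.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Average molecular weight of the free amino acid, Da. Only differences are
#: ever used, so the +18.02 Da water offset of the residue-mass convention
#: cancels and both conventions give identical relative values.
MOLECULAR_WEIGHT: dict[str, float] = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.15, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}

#: Kyte & Doolittle (1982) hydropathy index; positive = hydrophobic.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Residues whose side chains count as hydrophobic for core detection.
HYDROPHOBIC_AA: frozenset[str] = frozenset("AVLIMFWY")

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def _validate_table(mapping: Mapping[str, float], what: str) -> dict[str, float]:
    keys = set(mapping)
    if keys != STANDARD_AA:
        missing = sorted(STANDARD_AA - keys)
        extra = sorted(keys - STANDARD_AA)
        raise ValueError(
            f"{what} table must cover exactly the 20 standard residues; "
            f"missing={missing} extra={extra}"
        )
    return dict(mapping)


@dataclass(frozen=True)
class AAPropertyTable:
    """Per-residue molecular weight (Da) and hydropathy tables.

    ``mw`` holds free-amino-acid average molecular weights; ``hs`` holds
    Kyte-Doolittle hydropathy values (dimensionless, in [-4.5, 4.5] for the
    default scale). Either table may be overridden, e.g. with an alternative
    hydrophobicity scale loaded from CSV.
    """

    mw: Mapping[str, float] = field(default_factory=lambda: dict(MOLECULAR_WEIGHT))
    hs: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))

    def __post_init__(self) -> None:
        object.__setattr__(self, "mw", _validate_table(self.mw, "molecular-weight"))
        object.__setattr__(self, "hs", _validate_table(self.hs, "hydropathy"))
        if any(v <= 0 for v in self.mw.values()):
            raise ValueError("molecular weights must be positive")

    @staticmethod
    def load_scale(source: Union[str, Path, TextIO]) -> dict[str, float]:
        """Read a two-column (amino_acid, value) CSV into a property mapping."""
        close = False
        if isinstance(source, (str, Path)):
            handle = open(source, newline="")
            close = True
        else:
            handle = source
        try:
            reader = csv.reader(handle)
            out: dict[str, float] = {}
            for row in reader:
                if not row or row[0].startswith("#") or row[0] == "amino_acid":
                    continue
                out[row[0].strip().upper()] = float(row[1])
        finally:
            if close:
                handle.close()
        return _validate_table(out, "custom")

    def dump_scale(self, which: str, dest: Union[str, Path]) -> None:
        table = {"mw": self.mw, "hs": self.hs}[which]
        with open(dest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["amino_acid", "value"])
            for aa in AA_ORDER:
                writer.writerow([aa, table[aa]])


def require_standard(*residues: str) -> None:
    """Raise ``ValueError`` if any residue is not a standard one-letter code."""
    for aa in residues:
        if aa not in STANDARD_AA:
            raise ValueError(f"not a standard amino acid: {aa!r}")
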