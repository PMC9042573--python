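"""Shannon-entropy conservation scoring of region positions from an MSA.

The per-column entropy over the 20 standard residues, H = -sum p log2 p, is
converted to a raw conservation score 1 - H/log2(20) (1 = invariant column,
0 = uniform column) and min-max rescaled over the scored region to give the
relative evolutionary conservation score (ECS) in [0, 1]. The module consumes
a pre-built alignment (aligned FASTA or Clustal); running the aligner is out
of scope.

Gap handling (the default policy): gaps and ambiguous letters (B, Z, X, '.',
'-') are excluded from the column frequencies, and columns whose gap fraction
exceeds a configurable threshold are flagged low-confidence. All-gap columns
have undefined (NaN) entropy, never 0. These choices are emitted in the
profile metadata so downstream reports record them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from scipy.stats import entropy as _scipy_entropy

from .aminoacids import STANDARD_AA
from .records import RegionSpec

GAP_CHARS = frozenset("-.")
#: Letters treated as gaps (excluded and counted into the gap fraction).
AMBIGUOUS_AS_GAP = frozenset("BZXJUO*")

MAX_ENTROPY_BITS = math.log2(20)


@dataclass
class Alignment:
    """A parsed MSA: (identifier, aligned string) pairs plus the study protein's id."""

    sequences: list[tuple[str, str]]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        ids = [i for i, _ in self.sequences]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate sequence identifiers: {sorted(dup)}")
        length = len(self.sequences[0][1])
        for ident, seq in self.sequences:
            if len(seq) != length:
                raise ValueError(
                    f"ragged alignment: sequence {ident!r} has length {len(seq)}, "
                    f"expected {length}"
                )
        if self.reference_id is not None and self.reference_id not in ids:
            raise ValueError(f"reference_id {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    def get(self, ident: str) -> str:
        for i, s in self.sequences:
            if i == ident:
                return s
        raise KeyError(ident)

    def column(self, j: int) -> list[str]:
        return [s[j] for _, s in self.sequences]


def read_alignment(
    source: Union[str, Path, TextIO], fmt: str, reference_id: str | None = None
) -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    ``fmt`` is ``"fasta"`` or ``"clustal"``. Equal lengths are enforced here
    (naming the offending sequence) rather than delegated to the parser, so
    ragged FASTA input fails with a useful message.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"format must be 'fasta' or 'clustal', got {fmt!r}")
    close = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
    try:
        if fmt == "fasta":
            seqs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(handle, "fasta")]
        else:
            msa = AlignIO.read(handle, "clustal")
            seqs = [(r.id, str(r.seq).upper()) for r in msa]
    finally:
        if close:
            handle.close()
    return Alignment(seqs, reference_id=reference_id)


def _is_gap(symbol: str) -> bool:
    return symbol in GAP_CHARS or symbol in AMBIGUOUS_AS_GAP


def column_entropy(column: Sequence[str], gap_policy: str = "exclude") -> float:
    """Shannon entropy of one alignment column in bits.

    With the default ``"exclude"`` policy, frequencies are taken over the
    non-gap standard residues only. An all-gap column returns NaN.
    """
    if gap_policy != "exclude":
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    symbols = [s.upper() for s in column if not _is_gap(s.upper())]
    bad = [s for s in symbols if s not in STANDARD_AA]
    if bad:
        raise ValueError(f"non-standard residues in column: {sorted(set(bad))}")
    if not symbols:
        return float("nan")
    counts = pd.Series(symbols).value_counts().to_numpy(dtype=float)
    return float(_scipy_entropy(counts, base=2))


def _map_region_to_columns(msa: Alignment, region: RegionSpec) -> list[int]:
    """0-based alignment column of each region position, via the reference row."""
    ref = msa.get(msa.reference_id)
    degapped_cols = [j for j, s in enumerate(ref) if s not in GAP_CHARS]
    degapped = "".join(ref[j] for j in degapped_cols)

    target = region.wt_sequence
    # Prefer the offset implied by the region numbering when it matches.
    start0 = region.start - 1
    if degapped[start0 : start0 + len(target)] == target:
        offset = start0
    else:
        offset = degapped.find(target)
    if offset < 0:
        best_off, best_id = 0, -1
        for o in range(0, max(1, len(degapped) - len(target) + 1)):
            window = degapped[o : o + len(target)]
            ident = sum(a == b for a, b in zip(window, target))
            if ident > best_id:
                best_off, best_id = o, ident
        raise ValueError(
            f"region {region.protein_name} {region.start}-{region.end} not found in "
            f"degapped reference {msa.reference_id!r}; best local match at degapped "
            f"offset {best_off} with {best_id}/{len(target)} identities"
        )
    return [degapped_cols[offset + k] for k in range(len(target))]


def conservation_profile(
    msa: Alignment,
    region: RegionSpec,
    gap_policy: str = "exclude",
    gap_fraction_max: float = 0.5,
) -> pd.DataFrame:
    """Score every region position from its alignment column.

    Returns a frame indexed by region position with columns
    ``alignment_column`` (1-based), ``raw_entropy_bits``, ``raw_score``
    (1 - H/log2 20), ``relative_ecs`` (min-max over the region),
    ``gap_fraction`` and the boolean ``low_confidence`` flag for columns whose
    gap fraction exceeds ``gap_fraction_max``. If every raw score in the
    region is identical (degenerate case), the relative ECS is defined as 1.0
    throughout. Scoring metadata is attached as ``frame.attrs``.
    """
    if msa.reference_id is None:
        raise ValueError("alignment has no reference_id set")
    cols = _map_region_to_columns(msa, region)
    n_seq = len(msa.sequences)

    rows = []
    for pos, j in zip(region.positions, cols):
        column = [s.upper() for s in msa.column(j)]
        n_gap = sum(1 for s in column if _is_gap(s))
        h = column_entropy(column, gap_policy)
        raw = 1.0 - h / MAX_ENTROPY_BITS if not math.isnan(h) else float("nan")
        rows.append(
            {
                "alignment_column": j + 1,
                "raw_entropy_bits": h,
                "raw_score": raw,
                "gap_fraction": n_gap / n_seq,
            }
        )
    frame = pd.DataFrame(rows, index=list(region.positions))
    frame.index.name = "position"

    raw = frame["raw_score"]
    lo, hi = raw.min(), raw.max()
    if math.isnan(lo) or hi == lo:
        rel = pd.Series(np.where(raw.notna(), 1.0, np.nan), index=frame.index)
    else:
        rel = (raw - lo) / (hi - lo)
    frame["relative_ecs"] = rel
    frame["low_confidence"] = frame["gap_fraction"] > gap_fraction_max

    frame.attrs["metadata"] = {
        "entropy_base": 2,
        "gap_policy": gap_policy,
        "gap_fraction_max": gap_fraction_max,
        "relative_normalization": "min-max over scored region",
        "sequence_weighting": "uniform",
        "n_sequences": n_seq,
    }
    return frame
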