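"""Suppressor substitution records, matrices and count statistics.

A saturation-mutagenesis suppressor screen yields, per mutagenized region, a
list of single amino acid substitutions together with the number of
independent revertants (hits) in which each allele was recovered. This module
holds the data model for those lists, the TSV/CSV I/O, and the count-based
summaries: the position x 20-residue substitution matrix, the per-position
substitution-number profile, wild-type/mutant amino-acid preference counts,
and the screen-saturation statistic (fraction of alleles seen in >= 2
revertants).
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .aminoacids import AA_INDEX, AA_ORDER, STANDARD_AA

PathLike = Union[str, Path]


@dataclass(frozen=True)
class RegionSpec:
    """A contiguous mutagenized window of a protein, in 1-based numbering.

    ``wt_sequence`` covers positions ``start``..``end`` inclusive, so its
    length is ``end - start + 1``. All record validation is done against this
    window; internal 0-based offsets are derived and never exposed.
    """

    protein_name: str
    start: int
    end: int
    wt_sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        expected = self.end - self.start + 1
        if len(self.wt_sequence) != expected:
            raise ValueError(
                f"wt_sequence length {len(self.wt_sequence)} != region length {expected}"
            )
        bad = set(self.wt_sequence) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residues in wt_sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def wt_at(self, position: int) -> str:
        if not self.contains(position):
            raise ValueError(
                f"position {position} outside region {self.protein_name} "
                f"{self.start}-{self.end}"
            )
        return self.wt_sequence[position - self.start]

    def to_dict(self) -> dict:
        return {
            "protein_name": self.protein_name,
            "start": self.start,
            "end": self.end,
            "wt_sequence": self.wt_sequence,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegionSpec":
        return cls(d["protein_name"], int(d["start"]), int(d["end"]), d["wt_sequence"])


@dataclass(frozen=True)
class SubstitutionRecord:
    """One identified suppressor allele.

    ``hit_count`` is the number of independent revertants carrying the allele;
    0 means unknown (e.g. the record came from a presence-only table).
    """

    position: int
    wt_aa: str
    mut_aa: str
    hit_count: int = 0

    def __post_init__(self) -> None:
        if self.wt_aa not in STANDARD_AA:
            raise ValueError(f"non-standard wild-type residue {self.wt_aa!r}")
        if self.mut_aa not in STANDARD_AA:
            raise ValueError(f"non-standard mutant residue {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"identity substitution {self.wt_aa}{self.position}{self.mut_aa} is not a mutation"
            )
        if self.hit_count < 0:
            raise ValueError("hit_count must be >= 0")

    def validate_against(self, region: RegionSpec) -> None:
        if not region.contains(self.position):
            raise ValueError(
                f"position {self.position} outside region {region.protein_name} "
                f"{region.start}-{region.end}"
            )
        wt = region.wt_at(self.position)
        if wt != self.wt_aa:
            raise ValueError(
                f"wild-type mismatch at {self.position}: record says {self.wt_aa}, "
                f"region sequence has {wt}"
            )

    @property
    def allele(self) -> tuple[int, str]:
        return (self.position, self.mut_aa)

    def __str__(self) -> str:  # e.g. "S127R"
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def parse_substitution_table(
    source: Union[PathLike, TextIO, str], region: RegionSpec
) -> list[SubstitutionRecord]:
    """Parse a TSV of substitutions and validate every row against ``region``.

    Expected header columns: ``position  wt_aa  mut_aa  [hit_count]``; lines
    starting with ``#`` are ignored. Duplicate (position, mut_aa) rows are
    merged by summing their hit counts; unknown counts (0 or absent column)
    contribute 0 to the sum, so a group made entirely of unknown rows stays
    unknown. Rows with positions outside the region, a wild-type residue that
    contradicts the region sequence, an identity substitution, or any
    non-standard letter (B, Z, X, U, O or a ``*`` stop) are rejected with the
    offending row number — the screen design admits no premature stop codons
    among valid suppressor records.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()

    lines = text.splitlines()
    header: list[str] | None = None
    merged: dict[tuple[int, str], SubstitutionRecord] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if header is None:
            header = [f.lower() for f in fields]
            required = ["position", "wt_aa", "mut_aa"]
            if header[: len(required)] != required:
                raise ValueError(
                    f"line {lineno}: header must start with 'position wt_aa mut_aa', got {header}"
                )
            has_hits = len(header) > 3 and header[3] == "hit_count"
            continue
        try:
            position = int(fields[0])
        except ValueError:
            raise ValueError(f"line {lineno}: bad position {fields[0]!r}") from None
        wt_aa, mut_aa = fields[1].upper(), fields[2].upper()
        hit_count = 0
        if has_hits and len(fields) > 3:
            hit_count = int(fields[3])
        try:
            rec = SubstitutionRecord(position, wt_aa, mut_aa, hit_count)
            rec.validate_against(region)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        key = rec.allele
        if key in merged:
            prev = merged[key]
            merged[key] = SubstitutionRecord(
                position, wt_aa, mut_aa, prev.hit_count + rec.hit_count
            )
        else:
            merged[key] = rec
    return sorted(merged.values(), key=lambda r: (r.position, r.mut_aa))


def write_substitution_table(
    records: Iterable[SubstitutionRecord], dest: Union[PathLike, TextIO]
) -> None:
    """Write records in the TSV dialect accepted by :func:`parse_substitution_table`."""
    rows = ["position\twt_aa\tmut_aa\thit_count"]
    for rec in sorted(records, key=lambda r: (r.position, r.mut_aa)):
        rows.append(f"{rec.position}\t{rec.wt_aa}\t{rec.mut_aa}\t{rec.hit_count}")
    text = "\n".join(rows) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


class SubstitutionMatrix:
    """Position x 20-residue grid of suppressor counts for one region.

    The grid covers every (position, mutant residue) cell of the region; the
    wild-type cell at each position is structurally excluded (always 0).
    """

    def __init__(self, region: RegionSpec, counts: np.ndarray | None = None):
        self.region = region
        if counts is None:
            counts = np.zeros((len(AA_ORDER), len(region)), dtype=int)
        counts = np.asarray(counts, dtype=int)
        if counts.shape != (len(AA_ORDER), len(region)):
            raise ValueError(
                f"grid must be {len(AA_ORDER)} x {len(region)}, got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be >= 0")
        for j, pos in enumerate(region.positions):
            wt = region.wt_at(pos)
            if counts[AA_INDEX[wt], j] != 0:
                raise ValueError(f"wild-type cell ({pos}, {wt}) must be 0")
        self.counts = counts

    def count(self, position: int, mut_aa: str) -> int:
        return int(self.counts[AA_INDEX[mut_aa], position - self.region.start])

    @property
    def n_nonzero_cells(self) -> int:
        return int((self.counts > 0).sum())

    @classmethod
    def from_records(
        cls,
        records: Sequence[SubstitutionRecord],
        region: RegionSpec,
        presence_only: bool = False,
    ) -> "SubstitutionMatrix":
        """Build the matrix; ``presence_only`` records 1 per distinct allele
        (for tables whose hit counts are unknown)."""
        m = cls(region)
        for rec in records:
            rec.validate_against(region)
            j = rec.position - region.start
            i = AA_INDEX[rec.mut_aa]
            if presence_only:
                m.counts[i, j] = 1
            else:
                m.counts[i, j] += max(rec.hit_count, 1)
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(AA_ORDER), columns=list(self.region.positions)
        )

    def to_csv(self, dest: Union[PathLike, TextIO]) -> None:
        """Positions as ascending columns, the 20 residues as fixed-order rows."""
        frame = self.to_frame()
        frame.index.name = "mut_aa"
        frame.to_csv(dest)

    @classmethod
    def from_csv(
        cls, source: Union[PathLike, TextIO], region: RegionSpec
    ) -> "SubstitutionMatrix":
        frame = pd.read_csv(source, index_col=0)
        frame.columns = frame.columns.astype(int)
        if list(frame.index) != list(AA_ORDER):
            raise ValueError("matrix CSV rows must be the 20 residues in canonical order")
        if list(frame.columns) != list(region.positions):
            raise ValueError("matrix CSV columns do not match the region positions")
        return cls(region, frame.to_numpy())


def substitution_matrix(
    records: Sequence[SubstitutionRecord],
    region: RegionSpec,
    presence_only: bool = False,
) -> SubstitutionMatrix:
    return SubstitutionMatrix.from_records(records, region, presence_only=presence_only)


def substitution_number_profile(matrix: SubstitutionMatrix) -> pd.Series:
    """Per-position count of distinct mutant residues recovered (0..19)."""
    counts = (matrix.counts > 0).sum(axis=0)
    return pd.Series(counts, index=list(matrix.region.positions), name="substitution_number")


@dataclass(frozen=True)
class PreferenceCounts:
    """Counts of wild-type and mutant residues over a substitution list.

    Each distinct allele counts once, regardless of hit count, so both
    tallies sum to the number of records.
    """

    wt_counts: Mapping[str, int]
    mut_counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.wt_counts.values())

    def top_wt(self) -> str:
        return max(self.wt_counts, key=lambda a: (self.wt_counts[a], a))

    def top_mut(self) -> str:
        return max(self.mut_counts, key=lambda a: (self.mut_counts[a], a))


def amino_acid_preferences(records: Sequence[SubstitutionRecord]) -> PreferenceCounts:
    if not records:
        raise ValueError("cannot compute preferences for an empty record list")
    wt = Counter(r.wt_aa for r in records)
    mut = Counter(r.mut_aa for r in records)
    return PreferenceCounts(dict(wt), dict(mut))


def hit_saturation(records: Sequence[SubstitutionRecord]) -> float:
    """Fraction of alleles recovered in at least two independent revertants.

    A value near 1 indicates the screen is close to saturation. Records with
    unknown hit counts (0) are refused; use presence-only analyses for those.
    """
    if not records:
        raise ValueError("no records")
    for rec in records:
        if rec.hit_count == 0:
            raise ValueError(
                f"record {rec} has unknown hit count; saturation statistics need "
                "hit counts >= 1 — use presence-only mode for count-free tables"
            )
    n_multi = sum(1 for r in records if r.hit_count >= 2)
    return n_multi / len(records)
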