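"""Synthetic saturation-mutagenesis suppressor-screen generator.

Emulates the experimental design end to end: each region position receives a
library of random NNN codons (uniform over the 64 codons, so stops appear at
3/64), a hidden truth set defines which (position, mutant) alleles genuinely
suppress, selection removes everything else — identity codons, stop codons,
non-suppressor alleles — and each surviving library member is detected with a
per-allele Bernoulli probability (the hook for modelling non-uniform
revertant recovery). Survivors aggregate into substitution records with hit
counts, exported in the same TSV dialect the analysis pipeline parses, so
simulated screens flow through the real analysis unchanged.

Randomness contract: a single seeded NumPy generator; all draws are ordered
position-major, so identical seeds give bit-identical output across runs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .aminoacids import MOLECULAR_WEIGHT, KYTE_DOOLITTLE, STANDARD_AA
from .records import RegionSpec, SubstitutionRecord

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid for the 61 sense codons.
SENSE_CODONS: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)
STOP = "*"

#: Number of codons encoding each amino acid (degeneracy of the code).
CODON_MULTIPLICITY: dict[str, int] = dict(Counter(SENSE_CODONS.values()))


def translate_codon(codon: str) -> str:
    """Standard genetic code; returns the one-letter residue or ``"*"`` for stops."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"codon must be 3 letters over ACGT, got {codon!r}")
    if codon in STOP_CODONS:
        return STOP
    return SENSE_CODONS[codon]


Allele = tuple[int, str]


def _check_allele(allele: Allele, region: RegionSpec) -> None:
    pos, aa = allele
    if aa == STOP or aa not in STANDARD_AA:
        raise ValueError(f"truth allele ({pos}, {aa!r}) is not a standard residue")
    if not region.contains(pos):
        raise ValueError(f"truth allele position {pos} outside region")
    if region.wt_at(pos) == aa:
        raise ValueError(f"truth allele ({pos}, {aa}) is an identity substitution")


@dataclass(frozen=True)
class TruthSet:
    """Hidden ground-truth suppressor repertoire of a simulated screen.

    ``strengths`` optionally scales the detection probability per allele
    (selection strength); unlisted alleles use 1.0.
    """

    region: RegionSpec
    alleles: frozenset[Allele]
    strengths: Mapping[Allele, float] | None = None

    def __post_init__(self) -> None:
        for allele in self.alleles:
            _check_allele(allele, self.region)
        if self.strengths:
            for allele, s in self.strengths.items():
                _check_allele(allele, self.region)
                if not 0 <= s <= 1:
                    raise ValueError(f"strength for {allele} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, allele: Allele) -> bool:
        return allele in self.alleles

    def strength(self, allele: Allele) -> float:
        if self.strengths is None:
            return 1.0
        return float(self.strengths.get(allele, 1.0))

    def to_json(self, dest: Union[str, Path]) -> None:
        payload = {
            "region": self.region.to_dict(),
            "alleles": sorted([list(a) for a in self.alleles]),
            "strengths": (
                {f"{p}:{a}": s for (p, a), s in self.strengths.items()}
                if self.strengths
                else None
            ),
        }
        Path(dest).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "TruthSet":
        d = json.loads(Path(source).read_text())
        strengths = None
        if d.get("strengths"):
            strengths = {
                (int(k.split(":")[0]), k.split(":")[1]): float(v)
                for k, v in d["strengths"].items()
            }
        return cls(
            RegionSpec.from_dict(d["region"]),
            frozenset((int(p), a) for p, a in d["alleles"]),
            strengths,
        )


@dataclass(frozen=True)
class ScreenConfig:
    """Simulation parameters for one region's screen."""

    region: RegionSpec
    n_transformants_per_position: int
    detection_prob: Union[float, Mapping[Allele, float]] = 1.0
    seed: int = 0
    codon_model: str = "uniform_nnn"

    def __post_init__(self) -> None:
        if self.n_transformants_per_position <= 0:
            raise ValueError("n_transformants_per_position must be > 0")
        if self.codon_model != "uniform_nnn":
            raise ValueError(f"unknown codon model {self.codon_model!r}")
        probs = (
            [self.detection_prob]
            if isinstance(self.detection_prob, (int, float))
            else list(self.detection_prob.values())
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("detection probabilities must lie in [0, 1]")

    def prob(self, allele: Allele) -> float:
        if isinstance(self.detection_prob, (int, float)):
            return float(self.detection_prob)
        return float(self.detection_prob.get(allele, 0.0))

    def to_json(self, dest: Union[str, Path]) -> None:
        dp = self.detection_prob
        if not isinstance(dp, (int, float)):
            dp = {f"{p}:{a}": v for (p, a), v in dp.items()}
        payload = {
            "region": self.region.to_dict(),
            "n_transformants_per_position": self.n_transformants_per_position,
            "detection_prob": dp,
            "seed": self.seed,
            "codon_model": self.codon_model,
        }
        Path(dest).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ScreenConfig":
        d = json.loads(Path(source).read_text())
        dp = d["detection_prob"]
        if isinstance(dp, dict):
            dp = {(int(k.split(":")[0]), k.split(":")[1]): float(v) for k, v in dp.items()}
        return cls(
            RegionSpec.from_dict(d["region"]),
            int(d["n_transformants_per_position"]),
            dp,
            int(d["seed"]),
            d.get("codon_model", "uniform_nnn"),
        )


def build_nnn_library(
    region: RegionSpec,
    n_per_position: int,
    rng: Union[int, np.random.Generator],
) -> list[tuple[int, str]]:
    """Per-position multisets of uniform random NNN codons, position-major.

    Mirrors one mutagenesis reaction per position with equal library amounts
    mixed; the expected stop-codon fraction per position is 3/64.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    library: list[tuple[int, str]] = []
    for pos in region.positions:
        idx = rng.integers(0, 64, size=n_per_position)
        library.extend((pos, ALL_CODONS[i]) for i in idx)
    return library


@dataclass
class RevertantSample:
    """Surviving library members of a simulated screen, in sampling order."""

    region: RegionSpec
    survivors: list[tuple[int, str, str]]  # (position, codon, mut_aa)

    @property
    def records(self) -> list[SubstitutionRecord]:
        """Distinct alleles with hit counts (number of surviving members)."""
        tally = Counter((pos, aa) for pos, _, aa in self.survivors)
        return [
            SubstitutionRecord(pos, self.region.wt_at(pos), aa, n)
            for (pos, aa), n in sorted(tally.items())
        ]

    def __len__(self) -> int:
        return len(self.survivors)


def simulate_screen(
    library: Sequence[tuple[int, str]],
    truth: TruthSet,
    config: ScreenConfig,
    rng: Union[int, np.random.Generator, None] = None,
) -> RevertantSample:
    """Apply selection and detection to a codon library.

    A library member survives iff its translated residue differs from the
    wild type, is not a stop, its (position, residue) allele is in the truth
    set, and an independent Bernoulli(detection probability x allele
    strength) draw succeeds. Detection draws follow library order, so a fixed
    seed reproduces the sample exactly.
    """
    region = config.region
    if truth.region != region:
        raise ValueError("library/truth/config regions must agree")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    survivors: list[tuple[int, str, str]] = []
    for pos, codon in library:
        aa = translate_codon(codon)
        if aa == STOP or aa == region.wt_at(pos):
            continue
        allele = (pos, aa)
        if allele not in truth:
            continue
        p = config.prob(allele) * truth.strength(allele)
        if p >= 1.0 or rng.random() < p:
            survivors.append((pos, codon, aa))
    return RevertantSample(region, survivors)


def run_screen(config: ScreenConfig, truth: TruthSet) -> RevertantSample:
    """Build the library and run selection under one seeded generator."""
    rng = np.random.default_rng(config.seed)
    library = build_nnn_library(config.region, config.n_transformants_per_position, rng)
    return simulate_screen(library, truth, config, rng)


def saturation_curve(
    sample: RevertantSample, depths: Sequence[int]
) -> pd.DataFrame:
    """Collector-curve statistics at increasing sequencing depths.

    For each depth d (ascending), tallies the first d surviving revertants:
    distinct alleles found, and the fraction of those alleles seen in >= 2
    revertants (NaN when no alleles yet).
    """
    if list(depths) != sorted(depths):
        raise ValueError("depths must be ascending")
    rows = []
    for d in depths:
        tally = Counter((pos, aa) for pos, _, aa in sample.survivors[:d])
        distinct = len(tally)
        frac = (
            sum(1 for n in tally.values() if n >= 2) / distinct if distinct else float("nan")
        )
        rows.append({"depth": d, "distinct_alleles": distinct, "fraction_ge2": frac})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth-set constructors and analytic oracles


def random_truth_set(
    region: RegionSpec, n_alleles: int, rng: Union[int, np.random.Generator]
) -> TruthSet:
    """Uniform random truth set of ``n_alleles`` distinct non-identity alleles."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    candidates = [
        (pos, aa)
        for pos in region.positions
        for aa in sorted(STANDARD_AA)
        if aa != region.wt_at(pos)
    ]
    if n_alleles > len(candidates):
        raise ValueError("n_alleles exceeds the number of possible alleles")
    idx = rng.choice(len(candidates), size=n_alleles, replace=False)
    return TruthSet(region, frozenset(candidates[i] for i in sorted(idx)))


def hydrophilic_bias_truth(
    region: RegionSpec,
    biased_positions: Sequence[int],
    biased_mutants: str = "RKE",
) -> TruthSet:
    """Truth set with hydrophilic, bulky suppressors at designated positions.

    Biased positions receive the hydrophilic mutant set (arginine, lysine,
    glutamate by default, all heavier and far more hydrophilic than the
    hydrophobic wild types they replace). Every other position receives
    control mutants that are strictly heavier *and* strictly more hydrophobic
    than its wild type, so only the biased positions can show a negative mean
    relative hydropathy. Raises if a control position's wild type admits no
    such mutant (e.g. tryptophan or isoleucine wild types).
    """
    alleles: set[Allele] = set()
    for pos in region.positions:
        wt = region.wt_at(pos)
        if pos in biased_positions:
            for aa in biased_mutants:
                if aa != wt:
                    alleles.add((pos, aa))
        else:
            controls = [
                aa
                for aa in sorted(STANDARD_AA)
                if aa != wt
                and MOLECULAR_WEIGHT[aa] > MOLECULAR_WEIGHT[wt]
                and KYTE_DOOLITTLE[aa] > KYTE_DOOLITTLE[wt]
            ]
            if not controls:
                raise ValueError(
                    f"no control mutant heavier and more hydrophobic than wt {wt} at {pos}"
                )
            alleles.update((pos, aa) for aa in controls[:2])
    return TruthSet(region, frozenset(alleles))


def uniform_allele_detection(truth: TruthSet) -> dict[Allele, float]:
    """Detection probabilities making every truth allele equally likely per draw.

    A uniform NNN draw hits an allele with probability proportional to its
    codon multiplicity; setting the detection probability to the reciprocal
    multiplicity flattens this, so surviving draws land uniformly on the
    truth set — the regime in which the closed-form occupancy expectations
    apply exactly.
    """
    return {
        (pos, aa): 1.0 / CODON_MULTIPLICITY[aa] for pos, aa in truth.alleles
    }


def occupancy_expectation(n_alleles: int, n_draws: int) -> tuple[float, float]:
    """Closed-form occupancy for ``n_draws`` uniform draws over ``n_alleles``.

    Returns (expected number of alleles seen at least once, expected number
    seen at least twice): with q = 1 - 1/N,
    E[>=1] = N (1 - q^m) and E[>=2] = E[>=1] - m q^(m-1).
    """
    n, m = n_alleles, n_draws
    q = 1.0 - 1.0 / n
    e_ge1 = n * (1.0 - q**m)
    e_exactly1 = m * q ** (m - 1)
    return e_ge1, e_ge1 - e_exactly1
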