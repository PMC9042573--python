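import numpy as np
import pytest

from suppscan.fixtures import load_named_substitutions, load_region
from suppscan.records import RegionSpec, SubstitutionRecord


@pytest.fixture(scope="session")
def psm3_region() -> RegionSpec:
    return load_region("psm3_hcj")


@pytest.fixture(scope="session")
def rad21_region() -> RegionSpec:
    return load_region("rad21_ntd")


@pytest.fixture(scope="session")
def psm3_named_records(psm3_region):
    records, _ = load_named_substitutions("psm3_hcj")
    return records


@pytest.fixture
def toy_region() -> RegionSpec:
    # small window around a serine, mimicking a mutagenized stretch
    return RegionSpec("toy", 125, 132, "LESAGGLS")


def random_records(region: RegionSpec, n: int, rng: np.random.Generator,
                   with_hits: bool = True) -> list[SubstitutionRecord]:
    """Seeded random record sets for oracle comparisons."""
    from suppscan.aminoacids import AA_ORDER

    alleles = [
        (pos, aa)
        for pos in region.positions
        for aa in AA_ORDER
        if aa != region.wt_at(pos)
    ]
    idx = rng.choice(len(alleles), size=min(n, len(alleles)), replace=False)
    out = []
    for i in idx:
        pos, aa = alleles[i]
        hits = int(rng.integers(1, 6)) if with_hits else 0
        out.append(SubstitutionRecord(pos, region.wt_at(pos), aa, hits))
    return out
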