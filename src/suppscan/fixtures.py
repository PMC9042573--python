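"""Packaged example data: region specs and text-named substitution lists.

The two region fixtures describe the mutagenized windows of the fission-yeast
cohesin screen — Psm3 head-coiled coil junction (residues 95-168, 74 aa) and
the Rad21 kleisin N-terminal domain (residues 18-87, 70 aa). Their wild-type
sequences are SYNTHETIC scaffolds: the residues named in the published
description are pinned at their true positions and the remainder is a
deterministic filler, because the full native sequences are not part of this
package's inputs. The substitution TSVs are PARTIAL: they contain only the
alleles whose wild-type and mutant residues are both named in the running
text (hit counts unknown), not the complete screen output, which exists only
as figure images.
"""

from __future__ import annotations

from importlib import resources

from .records import RegionSpec, SubstitutionRecord, parse_substitution_table

_REGION_FILES = {
    "psm3_hcj": "psm3_hcj_region.synthetic.json",
    "rad21_ntd": "rad21_ntd_region.synthetic.json",
}
_SUBST_FILES = {
    "psm3_hcj": "psm3_hcj_substitutions.partial.tsv",
    "rad21_ntd": "rad21_ntd_substitutions.partial.tsv",
}


def _read(name: str) -> str:
    return (resources.files("suppscan") / "data" / name).read_text()


def load_region(name: str) -> RegionSpec:
    """``"psm3_hcj"`` or ``"rad21_ntd"`` (synthetic scaffold sequences)."""
    import json

    if name not in _REGION_FILES:
        raise KeyError(f"unknown region fixture {name!r}; choose from {sorted(_REGION_FILES)}")
    return RegionSpec.from_dict(json.loads(_read(_REGION_FILES[name])))


def load_named_substitutions(name: str) -> tuple[list[SubstitutionRecord], RegionSpec]:
    """Partial, text-named substitution list for a region fixture."""
    region = load_region(name)
    records = parse_substitution_table(_read(_SUBST_FILES[name]), region)
    return records, region
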