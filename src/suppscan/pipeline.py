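"""End-to-end screen-analysis pipeline and hotspot calling.

Ties the stages together: substitution table -> matrix and per-position
profile (substitution number, mean relative MW/HS), optional conservation
scoring from an MSA, optional structural annotation (interface contacts,
hydrophobic core), hotspot interval calling, and a machine-readable report
bundle (CSVs plus a run-metadata JSON recording every threshold actually
used). Given identical inputs and seed the bundle is byte-identical across
runs; stages without inputs are skipped with a warning and their columns
left empty.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aminoacids import AAPropertyTable
from .conservation import conservation_profile, read_alignment
from .physchem import mean_relative_profile
from .records import (
    RegionSpec,
    SubstitutionMatrix,
    parse_substitution_table,
    substitution_number_profile,
)
from .structure import (
    ChainMap,
    ContactThresholds,
    CoreParams,
    annotate_sites,
    annotation_summary,
    hydrophobic_core_residues,
    inter_chain_contacts,
    read_structure,
)

logger = logging.getLogger("suppscan")


def hotspot_call(
    profile: Union[pd.Series, Mapping[int, int]],
    min_count: int = 5,
    min_run: int = 3,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions with high substitution numbers.

    A hotspot is a run of at least ``min_run`` consecutive positions whose
    substitution number is at least ``min_count``. Intervals are inclusive,
    in region numbering, sorted ascending and never overlapping.
    """
    if not isinstance(profile, pd.Series):
        profile = pd.Series(dict(profile)).sort_index()
    positions = list(profile.index)
    if positions != list(range(positions[0], positions[0] + len(positions))):
        raise ValueError("profile must cover a contiguous region")
    intervals: list[tuple[int, int]] = []
    run_start: int | None = None
    for pos, count in profile.items():
        if count >= min_count:
            if run_start is None:
                run_start = pos
        else:
            if run_start is not None and pos - run_start >= min_run:
                intervals.append((run_start, pos - 1))
            run_start = None
    if run_start is not None and positions[-1] - run_start + 1 >= min_run:
        intervals.append((run_start, positions[-1]))
    return intervals


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; see ``from_file`` for the on-disk form."""

    region: RegionSpec
    substitutions: Union[str, Path]
    out_dir: Union[str, Path]
    msa_path: Union[str, Path, None] = None
    msa_format: str = "fasta"
    msa_reference_id: str | None = None
    structure_path: Union[str, Path, None] = None
    protein_chain: str | None = None
    partner_chain: str | None = None
    chain_offset: int = 0
    contact_thresholds: ContactThresholds = field(default_factory=ContactThresholds)
    core_params: CoreParams = field(default_factory=CoreParams)
    gap_fraction_max: float = 0.5
    hotspot_min_count: int = 5
    hotspot_min_run: int = 3
    seed: int = 0

    @classmethod
    def from_file(cls, path: Union[str, Path], **overrides: Any) -> "PipelineConfig":
        """Load a JSON or YAML config; keyword overrides win over file values."""
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        raw.update(overrides)
        region = RegionSpec.from_dict(raw.pop("region"))
        thresholds = ContactThresholds(**raw.pop("contact_thresholds", {}))
        core_raw = raw.pop("core_params", {})
        if "hydrophobic" in core_raw:
            core_raw["hydrophobic"] = frozenset(core_raw["hydrophobic"])
        core = CoreParams(**core_raw)
        msa = raw.pop("msa", None) or {}
        structure = raw.pop("structure", None) or {}
        return cls(
            region=region,
            substitutions=raw.pop("substitutions"),
            out_dir=raw.pop("out_dir", "suppscan_out"),
            msa_path=msa.get("path"),
            msa_format=msa.get("format", "fasta"),
            msa_reference_id=msa.get("reference_id"),
            structure_path=structure.get("path"),
            protein_chain=structure.get("protein_chain"),
            partner_chain=structure.get("partner_chain"),
            chain_offset=int(structure.get("offset", 0)),
            contact_thresholds=thresholds,
            core_params=core,
            **raw,
        )

    def validate(self) -> None:
        for label, p in [
            ("substitutions", self.substitutions),
            ("msa", self.msa_path),
            ("structure", self.structure_path),
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")


@dataclass
class ReportBundle:
    """Paths and in-memory frames of one pipeline run."""

    out_dir: Path
    paths: dict[str, Path]
    profile: pd.DataFrame
    hotspots: list[tuple[int, int]]
    metadata: dict


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage the config provides inputs for; see module docstring."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.perf_counter()

    def _stage(name: str) -> None:
        logger.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)

    try:
        region = config.region
        records = parse_substitution_table(config.substitutions, region)
        presence_only = any(r.hit_count == 0 for r in records)
        matrix = SubstitutionMatrix.from_records(
            records, region, presence_only=presence_only
        )
        paths = {"matrix": out_dir / "substitution_matrix.csv"}
        matrix.to_csv(paths["matrix"])
        written.append(paths["matrix"])
        _stage("matrix")

        table = AAPropertyTable()
        profile = pd.DataFrame(index=list(region.positions))
        profile.index.name = "position"
        profile["wt_aa"] = list(region.wt_sequence)
        profile["substitution_number"] = substitution_number_profile(matrix)
        profile["mean_rel_mw"] = mean_relative_profile(records, "mw", table, region)
        profile["mean_rel_hs"] = mean_relative_profile(records, "hs", table, region)
        _stage("physchem")

        cons_meta: dict | None = None
        if config.msa_path is not None:
            msa = read_alignment(
                config.msa_path, config.msa_format, reference_id=config.msa_reference_id
            )
            cons = conservation_profile(
                msa, region, gap_fraction_max=config.gap_fraction_max
            )
            for col in ("raw_entropy_bits", "raw_score", "relative_ecs", "gap_fraction"):
                profile[col] = cons[col]
            cons_meta = cons.attrs["metadata"]
            _stage("conservation")
        else:
            logger.warning("no MSA configured; conservation columns left empty")
            for col in ("raw_entropy_bits", "raw_score", "relative_ecs", "gap_fraction"):
                profile[col] = np.nan

        summary: dict | None = None
        if config.structure_path is not None:
            model = read_structure(config.structure_path)
            chain_map = ChainMap(config.protein_chain, config.chain_offset)
            contacts = []
            if config.partner_chain is not None:
                contacts = inter_chain_contacts(
                    model,
                    config.protein_chain,
                    config.partner_chain,
                    config.contact_thresholds,
                )
                contact_frame = pd.DataFrame(
                    [c.__dict__ for c in contacts]
                )
                paths["contacts"] = out_dir / "contacts.csv"
                contact_frame.to_csv(paths["contacts"], index=False)
                written.append(paths["contacts"])
            core = hydrophobic_core_residues(
                model, config.protein_chain, config.core_params
            )
            annotations = annotate_sites(records, contacts, core, chain_map, model)
            summary = annotation_summary(annotations)
            ann_frame = pd.DataFrame(
                {
                    "position": [a.position for a in annotations],
                    "categories": ["|".join(sorted(a.categories)) for a in annotations],
                    "n_supporting_contacts": [len(a.supporting_contacts) for a in annotations],
                    "burial_score": [a.burial_score for a in annotations],
                }
            )
            paths["annotations"] = out_dir / "site_annotations.csv"
            ann_frame.to_csv(paths["annotations"], index=False)
            written.append(paths["annotations"])
            cat_by_pos = {
                a.position: "|".join(sorted(a.categories)) for a in annotations
            }
            profile["site_category"] = [
                cat_by_pos.get(pos, "") for pos in profile.index
            ]
            _stage("structure")
        else:
            logger.warning("no structure configured; structural columns left empty")
            profile["site_category"] = ""

        paths["profile"] = out_dir / "position_profile.csv"
        profile.to_csv(paths["profile"])
        written.append(paths["profile"])

        hotspots = hotspot_call(
            profile["substitution_number"],
            min_count=config.hotspot_min_count,
            min_run=config.hotspot_min_run,
        )
        hs_frame = pd.DataFrame(hotspots, columns=["start", "end"])
        paths["hotspots"] = out_dir / "hotspots.csv"
        hs_frame.to_csv(paths["hotspots"], index=False)
        written.append(paths["hotspots"])
        _stage("hotspots")

        metadata = {
            "suppscan_version": __version__,
            "region": region.to_dict(),
            "n_records": len(records),
            "presence_only": presence_only,
            "seed": config.seed,
            "hotspot": {
                "min_count": config.hotspot_min_count,
                "min_run": config.hotspot_min_run,
            },
            "contact_thresholds": {
                "vdw": config.contact_thresholds.vdw,
                "hbond": config.contact_thresholds.hbond,
                "salt_bridge": config.contact_thresholds.salt_bridge,
            },
            "core_params": {
                "radius": config.core_params.radius,
                "burial_min": config.core_params.burial_min,
                "hydrophobic": "".join(sorted(config.core_params.hydrophobic)),
            },
            "conservation": cons_meta,
            "annotation_summary": summary,
            "hotspot_intervals": hotspots,
        }
        paths["metadata"] = out_dir / "run_metadata.json"
        paths["metadata"].write_text(json.dumps(metadata, indent=1, sort_keys=True))
        written.append(paths["metadata"])

        return ReportBundle(out_dir, paths, profile, hotspots, metadata)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
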