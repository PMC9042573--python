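"""Relative molecular-weight and hydrophobicity statistics of substitutions.

For a substitution wt->mut the relative value of a property is
``property(mut) - property(wt)``: a positive relative molecular weight means
the mutant residue is bulkier than the wild type, a negative relative
hydropathy (Kyte-Doolittle) means the position became more hydrophilic. The
per-position mean over all identified substitutions at that position is the
profile plotted along a mutagenized region; positions with no substitutions
are undefined (NaN), never zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .aminoacids import AAPropertyTable, require_standard
from .records import RegionSpec, SubstitutionRecord

_DEFAULT = AAPropertyTable()


def relative_mw(wt_aa: str, mut_aa: str, table: AAPropertyTable = _DEFAULT) -> float:
    """mw(mut) - mw(wt) in Da; antisymmetric in its arguments."""
    require_standard(wt_aa, mut_aa)
    return table.mw[mut_aa] - table.mw[wt_aa]


def relative_hs(wt_aa: str, mut_aa: str, table: AAPropertyTable = _DEFAULT) -> float:
    """hs(mut) - hs(wt), Kyte-Doolittle units; antisymmetric, range [-9, 9]."""
    require_standard(wt_aa, mut_aa)
    return table.hs[mut_aa] - table.hs[wt_aa]


def mean_relative_profile(
    records: Sequence[SubstitutionRecord],
    prop: str,
    table: AAPropertyTable = _DEFAULT,
    region: RegionSpec | None = None,
) -> pd.Series:
    """Per-position arithmetic mean of the relative property over records.

    ``prop`` is ``"mw"`` or ``"hs"``. Each distinct allele contributes once
    (hit counts do not weight the mean). If ``region`` is given the returned
    series covers every region position, with NaN at positions that have no
    substitutions; otherwise only mutated positions appear.
    """
    if prop == "mw":
        func = relative_mw
    elif prop == "hs":
        func = relative_hs
    else:
        raise ValueError(f"property must be 'mw' or 'hs', got {prop!r}")

    values: dict[int, list[float]] = {}
    for rec in records:
        if region is not None:
            rec.validate_against(region)
        values.setdefault(rec.position, []).append(func(rec.wt_aa, rec.mut_aa, table))

    means = {pos: float(np.mean(v)) for pos, v in values.items()}
    if region is not None:
        index = list(region.positions)
    else:
        index = sorted(means)
    data = [means.get(pos, np.nan) for pos in index]
    return pd.Series(data, index=index, name=f"mean_rel_{prop}")
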