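"""Convenience orchestration shared by the CLI and the analysis drivers."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .calling import call_variants
from .coords import CoordinateWindow, ReferenceSequence
from .haplotree import MacroGroupTable, MotifTree, classify
from .variants import HaplotypeProfile, format_variants, mask_heteroplasmies


def profiles_from_records(
    records: Sequence[tuple[str, str, str]],
    reference: ReferenceSequence,
    window: CoordinateWindow,
    mask: bool = True,
) -> list[HaplotypeProfile]:
    """Call variants for (sample_id, sequence, population) records."""
    out = []
    for sid, seq, pop in records:
        prof = call_variants(seq, reference, window, sample_id=sid, population=pop)
        out.append(mask_heteroplasmies(prof) if mask else prof)
    return out


def classify_profiles(
    profiles: Sequence[HaplotypeProfile],
    tree: MotifTree,
    table: MacroGroupTable,
) -> pd.DataFrame:
    """Classify every profile; one row per sample with macro and origin."""
    rows = []
    for prof in profiles:
        res = classify(mask_heteroplasmies(prof), tree)
        macro = table.macro_group(res.haplogroup)
        rows.append(
            {
                "sample_id": prof.sample_id,
                "population": prof.population,
                "haplogroup": res.haplogroup,
                "macro": macro,
                "origin": table.origin_of(macro),
                "score": res.score,
                "private_variants": format_variants(res.private),
            }
        )
    return pd.DataFrame(rows)
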