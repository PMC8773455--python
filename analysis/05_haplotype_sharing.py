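#!/usr/bin/env python
"""Pairwise haplotype-sharing ratios between population groups, overall and
partitioned by eastern-Asian vs western-Eurasian haplogroup origin."""

from pathlib import Path

import pandas as pd

from mtlineage.coords import CONTROL_REGION
from mtlineage.io import read_variant_table
from mtlineage.sharing import haplotype_sets, sharing_long_table, sharing_matrix

IN = Path("results/analysis/02_classification")
OUT = Path("results/analysis/05_sharing")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with open(IN / "profiles.tsv") as fh:
        profiles = read_variant_table(fh)
    cls = pd.read_csv(IN / "classifications.tsv", sep="\t")
    origins = dict(zip(cls.sample_id, cls.origin))

    tables = []
    for origin_filter in ("all", "EAs", "WEu"):
        sets = haplotype_sets(profiles, CONTROL_REGION, origin_filter, origins)
        sets = {p: s for p, s in sets.items() if s}
        sm = sharing_matrix(sets, origin_filter)
        sm.to_frame().to_csv(OUT / f"sharing_{origin_filter}.tsv", sep="\t")
        long = sharing_long_table(sets, origin_filter)
        tables.append(long)
        top = long.sort_values("ratio_sym", ascending=False).iloc[0]
        print(f"{origin_filter:>4}: {len(sets)} groups; highest sharing "
              f"{top.pop_a}~{top.pop_b} (ratio_sym={top.ratio_sym:.3f}, "
              f"shared={top.shared})")
    pd.concat(tables).to_csv(OUT / "sharing_long.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
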