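#!/usr/bin/env python
"""Diversity summaries: segregating sites, haplotype and nucleotide
diversity, overall and per population group (complete-deletion filtering)."""

from pathlib import Path

from mtlineage.coords import CONTROL_REGION
from mtlineage.io import load_reference, read_variant_table
from mtlineage.popgen import build_aligned_matrix, diversity_table

IN = Path("results/analysis/02_classification")
OUT = Path("results/analysis/03_diversity")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with open(IN / "profiles.tsv") as fh:
        profiles = read_variant_table(fh)
    matrix = build_aligned_matrix(profiles, load_reference(), CONTROL_REGION)
    table = diversity_table(matrix)
    table.to_csv(OUT / "diversity.tsv", sep="\t", index=False)
    overall = table[table.population == "ALL"].iloc[0]
    print(f"overall: n={overall.n}, {overall.k_hap} distinct haplotypes, "
          f"S={overall.S}, Hd={overall.Hd:.3f}, Pi={overall.Pi:.5f} "
          f"over {overall.usable_sites} usable sites")
    sub = table[(table.population != "ALL") & (table.n >= 30)]
    lo, hi = sub.loc[sub.Pi.idxmin()], sub.loc[sub.Pi.idxmax()]
    print(f"lowest Pi: {lo.population} ({lo.Pi:.5f}); "
          f"highest Pi: {hi.population} ({hi.Pi:.5f})")


if __name__ == "__main__":
    main()
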