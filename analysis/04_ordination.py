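#!/usr/bin/env python
"""Ordination of population structure: PCA on macro-haplogroup frequencies
and classical MDS on the mean p-distance matrix (populations with n>=30)."""

from pathlib import Path

import pandas as pd

from mtlineage.coords import CONTROL_REGION
from mtlineage.io import load_reference, read_variant_table
from mtlineage.ordination import build_frequency_matrix, classical_mds, pca
from mtlineage.popgen import build_aligned_matrix, build_distance_matrix

IN = Path("results/analysis/02_classification")
OUT = Path("results/analysis/04_ordination")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cls = pd.read_csv(IN / "classifications.tsv", sep="\t")
    freq = build_frequency_matrix(cls, min_n=30)
    freq.to_csv(OUT / "macro_frequencies.tsv", sep="\t")
    res = pca(freq, n_axes=2)
    res.coordinates.to_csv(OUT / "pca_coordinates.tsv", sep="\t")
    print(f"PCA over {freq.shape[0]} populations: "
          f"PC1 {res.explained[0]:.1%}, PC2 {res.explained[1]:.1%} of variance")
    pc2 = res.coordinates["axis2"]
    print(f"  PC2 extremes: {pc2.idxmax()} ({pc2.max():.3f}) vs "
          f"{pc2.idxmin()} ({pc2.min():.3f})")

    with open(IN / "profiles.tsv") as fh:
        profiles = read_variant_table(fh)
    matrix = build_aligned_matrix(profiles, load_reference(), CONTROL_REGION)
    dist = build_distance_matrix(matrix, min_n=30)
    dist.to_frame().to_csv(OUT / "p_distance.tsv", sep="\t")
    mds = classical_mds(dist, n_axes=2)
    mds.coordinates.to_csv(OUT / "mds_coordinates.tsv", sep="\t")
    print(f"MDS over {len(dist.labels)} populations: axis1 carries "
          f"{mds.explained[0]:.1%} of the positive spectrum")


if __name__ == "__main__":
    main()
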