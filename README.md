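# mtlineage

Matrilineal population structure from human mitochondrial control-region
sequences: rCRS-relative variant profiling, motif-based haplogroup
classification, diversity and distance statistics, ordination, pairwise
haplotype sharing, and spatiotemporal tracing of lineage arrivals through
ancient mitogenomes.

The package is aimed at population geneticists working with large
control-region surveys of the kind used to study maternal gene flow across
Eurasia — cohorts of hypervariable-segment or full control-region (CR,
np 16024–576) haplotypes labelled by sampling population, classified against
a PhyloTree-style motif tree into haplogroups with eastern-Asian (EAs) or
western-Eurasian (WEu) geographic origins.

## What it computes

Each sample is reduced to a **haplotype profile**: the set of rCRS-coordinate
variants (`16189C`, `16193.1C`, `249del`) obtained from a banded global
alignment of its sequence to the reference window, with indels normalised to
the 3′-most position of their homopolymer run (the forensic reporting
convention) and heteroplasmic IUPAC bases masked to N. On top of profiles:

- **Haplogroup classification.** Each node of a motif tree carries the
  mutations expected on its branch; the cumulative motif of a node is the
  sequential application along the root path (back mutations, `!`, cancel
  earlier expectations). A profile is assigned the node maximising
  `(matched − ½·missing_in_window) / (matched + private)`, with expectations
  restricted to the profile's coverage window so coding-region motif content
  never penalises control-region-only data. Haplogroup names map to 18
  macro-haplogroups (A, B, D, G, JT, L3\*, M\*, M7, M8, M9, N1, N2, N9, R\*,
  R0, R9, U, X) by longest-prefix rules, each with an EAs or WEu origin.
- **Diversity.** Segregating sites *S*, haplotype diversity
  *Hd = n(1 − Σpᵢ²)/(n − 1)* and nucleotide diversity
  *π = Σ_{i<j} d_ij / (C(n,2)·L)* over gap/N-free columns (complete
  deletion); population mean p-distances with pairwise deletion.
- **Ordination.** Column-centred PCA of population × macro-haplogroup
  frequency matrices, and classical (Torgerson) MDS of distance matrices.
- **Haplotype sharing.** For populations A and B, `shared = |A∩B|` over
  distinct haplotype keys, with directional ratios `shared/|A|`, `shared/|B|`
  and their mean as the headline symmetric ratio — overall and partitioned
  by EAs/WEu origin.
- **Ancient-lineage tracing.** Given dated, georeferenced ancient
  mitogenomes, each lineage is classified as present in a longitude band of
  interest before a calendar cutoff (default 1000 BCE), a later arrival, or
  absent; arrivals whose earliest band record is preceded by a strictly
  older record 20–40° of longitude to the west are flagged as consistent
  with an overland west-to-east trade route.

A synthetic-data module generates cohorts with known truth (haplogroup
draws from per-population frequency vectors, Poisson private substitutions,
optional heteroplasmy) and planted ancient trajectories, so every stage has
a parameter-recovery test surface. The packaged reference and motif tree are
**synthetic stand-ins** with realistic geometry (see `docs/methods.md`).

## Worked example

The numbered drivers under `analysis/` run the whole study on the
study-shaped synthetic cohort (20 provinces plus an unlabelled group,
2,420 samples):

```
$ python analysis/01_simulate_cohort.py --seed 1
simulated 2420 samples in 21 groups (largest: Khovd, n=429)
$ python analysis/02_classify_haplogroups.py
classified 2420 samples into 41 lineages, 18 macro-haplogroups
recovery vs simulation truth: 100.0%; WEu share: 23.6%
$ python analysis/03_diversity.py
overall: n=2420, 1495 distinct haplotypes, S=948, Hd=0.973, Pi=0.00615 over 1076 usable sites
$ python analysis/06_ancient_trace.py
traced 19 lineages: 5 present before 1000 BCE, 14 later arrivals, 6 route-consistent
route-consistent lineages: H5a1, J1b2, T2g, U2e1b, U4b1a1a1, U4b1a4
```

Reading the output: classification recovers every generating haplogroup
despite one expected private substitution per sample; the cohort is ~24%
western-Eurasian, concentrated in the westernmost provinces (visible on PC2
of `04_ordination.py`); and of the 14 lineages that reach the
Mongolia-and-nearby longitude band (85–125 °E) after 1000 BCE, six follow a
west-to-east trajectory whose longitude offset falls in the 20–40° window.

The same stages are available as subcommands of the `mtlineage` CLI
(`simulate`, `classify`, `diversity`, `distance`, `pca`, `mds`, `share`,
`trace`, `all`), each writing TSV/JSON artifacts plus a run manifest.

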