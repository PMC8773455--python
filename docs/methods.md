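# Methods

## Coordinate system and variant representation

All positions are 1-based rCRS coordinates on a circular 16,569-bp molecule;
windows are closed intervals that may span the origin (the control region is
np 16024–576, 1,122 bp; HVS1 is np 16024–16365; cross-dataset comparisons
default to the 546-bp window np 16024–16569). Variants use forensic/EMPOP
text notation: `16189C` (substitution), `16193.1C` (first inserted base
after np 16193), `249del` (deletion). These are PhyloTree/EMPOP community
conventions; nothing in the statistics depends on them beyond consistency.

**Packaged reference.** The repository cannot redistribute NC_012920.1, so
the packaged reference (`data/synthetic_rcrs_like.fasta`) is a synthetic
16,569-bp sequence with rCRS geometry: correct length, circularity, and the
two classic poly-C tracts (np 303–315 with T at 310; np 16184–16193 with T
at 16189) that exercise homopolymer indel placement. Every analysis accepts
a user-supplied reference FASTA of canonical length, so the true rCRS can be
dropped in without code changes. All coordinate anchors used by the fixtures
(16184, 16291, 9110, 1654, 9377, 11152) are preserved.

## Variant calling

Sequences are globally aligned to the reference window with a banded
edit-distance alignment (edlib, ceiling 60 edits by default; sequences whose
length differs from the window by more than ±20 bp are rejected, as are
alignments exceeding the ceiling). The alignment path is then normalised by
shifting every indel 3′-wards while the indel base equals the next reference
base — a cost-preserving exchange — so indels always land at the 3′-most
position of their homopolymer run. Insertions 5′ of the first reference base
of the window are trimmed (they lie outside the coverage window). Two design
consequences are deliberate:

- Adjacent substitutions can, in rare sequence contexts, admit a cost-equal
  insertion+deletion representation; the aligner may then report the indel
  form. The packaged motif tree therefore keeps motif positions ≥3 bp apart,
  which makes motif recovery exact; private mutations in synthetic data can
  still occasionally hit such contexts, which is part of why the noisy
  recovery criterion is ≥95% rather than 100%.
- Ambiguity codes (heteroplasmies) align as mismatches and are called as
  substitutions carrying the IUPAC code; `mask_heteroplasmies` converts them
  to N before classification, diversity and sharing, and masking is
  idempotent.

## Motif tree and classification

The packaged tree (`data/minitree.tsv`) is a synthetic PhyloTree-build-17
style subset: 104 nodes whose names and topology follow published
haplogroup nomenclature (including HV13b1, U5b1c2, H1b/H1c/H1j, H5a1,
U5a1, the U4b1a clade, and representatives of all 18 macro-haplogroups),
but whose branch motifs are generated transitions on the synthetic
reference — real build-17 motifs are not redistributable from text alone.
Two branches are anchored to their published defining positions: HV13b1
(coding 1654/9377/11152 plus control-region 16184/16291 on top of the HV13b
background) and U5b1c2 (the transition at np 9110). Every other branch
carries 1–2 control-region positions (plus optionally one coding position),
which makes every leaf uniquely identifiable from control-region data alone;
U5b1c2, whose own branch is coding-only, is still recovered on
control-region windows through the depth tie-break described below.

Cumulative motifs apply branch motifs sequentially from the root; a `!`
token cancels any earlier expectation at its position, and a lineage can
re-add a variant below a reversion by listing it again.

Classification scores every node:
`score = (matched − w·unmatched_expected_in_window) / (matched + private + 1e−9)`
with `w = 0.5` by default. Expectations are restricted to the profile's
coverage window; observed N substitutions match any expected base at their
position. Ties break to the deeper node, then the lexicographically smaller
name. The weight and the rule are this package's own (the classifiers used
in the field do not publish a single canonical score); `w` is a parameter of
`classify`. An empty profile classifies to the reference node, which the
macro table maps to R0/WEu (the reference haplotype is an H2a2a1-like
lineage).

The macro-group table (`data/macrogroups.tsv`) implements longest-prefix
matching onto the 18 macro labels and their origins
(WEu = {JT, N1, N2, R0, U, X}; EAs = the rest, including L3\*, M\* and R\*,
whose origin assignment is a defensible default rather than a published
fact — the table is user-overridable).

## Diversity and distances

Site filtering is complete-deletion (drop any column containing a gap or N
in any row) for segregating sites, Hd and π, and pairwise-deletion for
p-distances — matching the common defaults of the programs used for these
statistics in the field (DnaSP-style diversity, MEGA-style distances).
Hd uses the n/(n−1) small-sample correction; π is the plain all-pairs
per-site estimator with no additional correction. π is computed over
collapsed distinct haplotypes with multiplicities, which is algebraically
identical to the all-pairs sum and much faster on cohorts dominated by
repeated haplotypes. Haplotype identity is exact string equality over the
retained columns (N is a literal character after masking) — consistent with
the sharing module, where wildcard-N matching would break transitivity.
Population distance matrices drop groups below a configurable minimum
(default 30 samples) with a logged warning.

## Ordination

PCA centres columns without variance scaling (frequencies share a unit) and
eigendecomposes the covariance of rows; explained fractions are eigenvalue
shares of the total variance. Classical MDS double-centres the squared
distance matrix (B = −½ J D² J) and embeds on the positive eigenpairs,
truncating negative eigenvalues with a warning. Axis signs are arbitrary in
both methods, so a deterministic convention is imposed for reproducibility:
the largest-magnitude loading (PCA) or coordinate (MDS) of each axis is made
positive. No compositional transform (CLR/logit) is applied to frequencies.

## Haplotype sharing

The headline statistic for a pair is the symmetric ratio
`(|A∩B|/|A| + |A∩B|/|B|)/2` over distinct haplotype keys; both directional
ratios and the raw count are always written so any alternative reading of
"shared over total per group" can be reconstructed from the output. Sharing
defaults to the 546-bp comparison window, the natural common denominator of
heterogeneous control-region datasets.

## Ancient-lineage tracing

Dates are signed calendar years CE (−1000 = 1000 BCE); before-present dates
convert with the 1950 datum at parse time, and radiocarbon uncertainty is
ignored (point dates). A lineage matches a record when the record's
haplogroup is the lineage or nested within it — via the motif tree when one
is supplied, otherwise by clade-name prefix with a digit/letter token
boundary (`H5a1` matches `H5a1a`, not `H51`). For each lineage: the earliest
matching record inside the longitude band (default 85–125 °E, a
"Mongolia and nearby" band; fully configurable) sets the status relative to
the cutoff (default −1000); the earliest-dated matching record west of it
(ties broken westernmost) is the precursor; an arrival is route-consistent
when the precursor is strictly older and 20–40° further west. The band, the
cutoff and the offset window are parameters, not constants.

## Synthetic data

The generator emulates a large province-structured control-region survey:
per-population haplogroup frequency vectors over the packaged tree's leaves,
sequence = reference window edited by the cumulative motif, Poisson(λ)
private substitutions at uniform non-motif positions (substitution-only, so
alignment is exercised separately from classification; indel calling has
dedicated fixtures), and with configurable probability one heteroplasmic
position encoded as the two-base IUPAC mix of derived and reference base.
The default cohort mirrors the shape of a 2,420-sample, 20-province
Mongolian survey, with the western-Eurasian share enriched in the
westernmost provinces (~22–24% cohort-wide) — qualitative realism for
demos, not a fit to any dataset. Everything is reproducible from a single
integer seed.

What the generator does **not** model: mutational hotspots, rate
heterogeneity, indel polymorphism, coalescent genealogy, sequencing error
beyond heteroplasmy codes, or missing data patterns. Passing recovery tests
therefore demonstrates correctness of the pipeline's bookkeeping and
statistics under clean conditions, not robustness to every artefact of real
control-region data.

The planted-sharing generator gives two populations exact distinct-haplotype
counts with a Binomial(n, f) number of copied haplotypes, so the recovered
shared count can be asserted exactly and the symmetric ratio within 3
binomial standard errors. The ancient generator realises per-lineage
trajectory specs and records the implied truth status independently of the
tracing code.

## Problem sizes and numerical choices

The test suite runs the full statistics oracle comparison on 100 random
instances of ≤12 samples × ≤60 columns (tolerance 1e−9), classification
recovery on cohorts of 300 (noiseless) and 1,000 (λ = 1) samples, and the
complete pipeline on the 2,420-sample cohort in the acceptance script —
sizes chosen so the whole suite runs in well under a minute on one CPU.
Degenerate inputs fail loudly: diversity needs n ≥ 2 and ≥1 usable column,
distance matrices need ≥2 surviving populations, MDS needs a positive
eigenvalue, sharing needs non-empty key sets, and classification needs a
non-empty tree.

## Known limitations

- The packaged tree is a subset; real surveys should supply a full
  PhyloTree-dialect file (same TSV format) and, ideally, the true rCRS.
- The classifier is deliberately simpler than Kulczynski-style weighted
  matchers; on real data with hotspot recurrence it will disagree with them
  on edge cases, as any pair of classifiers does.
- The sharing semantics (distinct haplotypes per group) is one documented
  choice among several defensible readings; all raw quantities are emitted.
- Trace results treat dates as exact; calibrated uncertainty intervals are
  out of scope.
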