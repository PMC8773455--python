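"""Diversity and distance statistics on aligned control-region matrices.

The aligned matrix is materialised from variant profiles over a common
window: one column per reference position plus one per observed insertion
site. Site filtering follows two modes: complete deletion (drop a column if
any row carries a gap or N) for segregating sites, haplotype diversity and
nucleotide diversity; pairwise deletion for p-distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coords import CoordinateWindow, ReferenceSequence
from .variants import DELETION, INSERTION, SUBSTITUTION, HaplotypeProfile

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class AlignedMatrix:
    sample_ids: list[str]
    populations: list[str]
    columns: list[tuple]  # (position, insertion_index); index 0 = ref column
    data: np.ndarray  # (n_samples, n_columns) of single characters

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def rows_for(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.populations) if p == population]
        )

    def subset(self, populations: Iterable[str]) -> "AlignedMatrix":
        keep = set(populations)
        idx = [i for i, p in enumerate(self.populations) if p in keep]
        return AlignedMatrix(
            [self.sample_ids[i] for i in idx],
            [self.populations[i] for i in idx],
            self.columns,
            self.data[idx],
        )


def build_aligned_matrix(
    profiles: Sequence[HaplotypeProfile],
    reference: ReferenceSequence,
    window: CoordinateWindow,
) -> AlignedMatrix:
    """Materialise profiles as a rectangular character matrix over *window*.

    Samples lacking an insertion observed in another sample receive a gap in
    that insertion column; deletions become gaps in the reference column.
    """
    positions = window.positions()
    pos_index = {p: i for i, p in enumerate(positions)}
    ins_sites = sorted(
        {
            (v.position, v.insertion_index)
            for pr in profiles
            for v in pr.variants
            if v.kind == INSERTION
        },
        key=lambda s: (pos_index.get(s[0], -1), s[1]),
    )
    columns: list[tuple] = [(p, 0) for p in positions]
    # interleave insertion columns after their anchor position
    for site in ins_sites:
        anchor_i = pos_index.get(site[0])
        if anchor_i is None:
            continue
        insert_at = columns.index((site[0], site[1] - 1)) + 1 if site[1] > 1 else anchor_i + 1
        while insert_at < len(columns) and columns[insert_at][0] == site[0] and columns[insert_at][1] < site[1]:
            insert_at += 1
        columns.insert(insert_at, site)
    col_index = {c: i for i, c in enumerate(columns)}
    ref_row = np.array(
        [reference.base_at(p) if k == 0 else GAP for p, k in columns], dtype="U1"
    )
    data = np.tile(ref_row, (len(profiles), 1))
    for r, pr in enumerate(profiles):
        for v in pr.variants:
            if v.kind == SUBSTITUTION:
                data[r, col_index[(v.position, 0)]] = v.derived_base
            elif v.kind == DELETION:
                data[r, col_index[(v.position, 0)]] = GAP
            elif (v.position, v.insertion_index) in col_index:
                data[r, col_index[(v.position, v.insertion_index)]] = v.derived_base
    return AlignedMatrix(
        [p.sample_id for p in profiles],
        [p.population for p in profiles],
        columns,
        data,
    )


def usable_columns(matrix: AlignedMatrix) -> np.ndarray:
    """Indices of columns free of gaps and Ns in every row (complete deletion)."""
    bad = (matrix.data == GAP) | (matrix.data == "N")
    return np.flatnonzero(~bad.any(axis=0))


def segregating_sites(matrix: AlignedMatrix, cols: np.ndarray | None = None) -> int:
    """Number of usable columns with at least two distinct bases."""
    if cols is None:
        cols = usable_columns(matrix)
    if len(cols) == 0 or matrix.n == 0:
        return 0
    sub = matrix.data[:, cols]
    return int(np.sum((sub != sub[0]).any(axis=0)))


def _row_strings(matrix: AlignedMatrix, cols: np.ndarray) -> list[str]:
    sub = matrix.data[:, cols]
    return ["".join(row) for row in sub]


def haplotype_counts(matrix: AlignedMatrix, cols: np.ndarray | None = None):
    if cols is None:
        cols = usable_columns(matrix)
    counts: dict[str, int] = {}
    for s in _row_strings(matrix, cols):
        counts[s] = counts.get(s, 0) + 1
    return counts


def haplotype_diversity(matrix: AlignedMatrix, cols: np.ndarray | None = None) -> float:
    """Hd = n(1 - sum p_i^2)/(n - 1) over distinct row strings."""
    n = matrix.n
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    counts = haplotype_counts(matrix, cols)
    p2 = sum((c / n) ** 2 for c in counts.values())
    return n * (1.0 - p2) / (n - 1)


def nucleotide_diversity(matrix: AlignedMatrix, cols: np.ndarray | None = None) -> float:
    """Per-site mean pairwise difference over usable columns.

    Pi = sum_{i<j} d_ij / (C(n,2) * L). Computed over collapsed distinct
    haplotypes with multiplicities, which is exact and much faster for large
    cohorts dominated by repeated haplotypes.
    """
    n = matrix.n
    if n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    if cols is None:
        cols = usable_columns(matrix)
    L = len(cols)
    if L == 0:
        raise ValueError("no usable columns for nucleotide diversity")
    counts = haplotype_counts(matrix, cols)
    haps = list(counts)
    mult = np.array([counts[h] for h in haps], dtype=float)
    k = len(haps)
    if k == 1:
        return 0.0
    arr = np.frombuffer("".join(haps).encode(), dtype="S1").reshape(k, L)
    total = 0.0
    for i in range(k):
        diffs = (arr[i + 1 :] != arr[i]).sum(axis=1)
        total += float(np.dot(diffs, mult[i + 1 :])) * mult[i]
    pairs = n * (n - 1) / 2
    return total / (pairs * L)


def _encode_pairwise(matrix: AlignedMatrix) -> np.ndarray:
    """Integer encoding with -1 for gap/N (sites excluded pairwise)."""
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    enc = np.full(matrix.data.shape, -1, dtype=np.int8)
    for b, code in lut.items():
        enc[matrix.data == b] = code
    return enc


def mean_p_distance(
    matrix: AlignedMatrix,
    group_a: str,
    group_b: str,
    _enc: np.ndarray | None = None,
) -> float:
    """Mean pairwise p-distance between two populations (pairwise deletion)."""
    if group_b < group_a:  # fixed evaluation order => exact symmetry
        group_a, group_b = group_b, group_a
    ia, ib = matrix.rows_for(group_a), matrix.rows_for(group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"empty population among {group_a!r}, {group_b!r}")
    enc = _encode_pairwise(matrix) if _enc is None else _enc
    A, B = enc[ia], enc[ib]
    dists: list[np.ndarray] = []
    same = group_a == group_b
    if same and len(ia) < 2:
        return 0.0
    # one vectorised sweep per row of A against the (remaining) rows of B
    for r in range(len(ia)):
        other = B[r + 1 :] if same else B
        if len(other) == 0:
            continue
        a = A[r]
        ok = (a >= 0) & (other >= 0)
        ncomp = ok.sum(axis=1)
        if (ncomp == 0).any():
            j = int(np.flatnonzero(ncomp == 0)[0])
            jj = ib[r + 1 + j] if same else ib[j]
            raise ValueError(
                f"pair ({matrix.sample_ids[ia[r]]}, {matrix.sample_ids[jj]}) "
                "has no comparable sites"
            )
        diffs = ((a != other) & ok).sum(axis=1)
        dists.append(diffs / ncomp)
    return float(np.mean(np.concatenate(dists)))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if (v < 0).any() or not np.allclose(np.diag(v), 0):
            raise ValueError("distances must be non-negative, zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def build_distance_matrix(
    matrix: AlignedMatrix,
    populations: Sequence[str] | None = None,
    min_n: int = 30,
) -> DistanceMatrix:
    """Population p-distance matrix; groups below *min_n* are dropped."""
    if populations is None:
        populations = sorted(set(matrix.populations))
    surviving = []
    for pop in populations:
        n = len(matrix.rows_for(pop))
        if n < min_n:
            logger.warning(
                "dropping population %r (n=%d < %d)", pop, n, min_n
            )
        else:
            surviving.append(pop)
    if len(surviving) < 2:
        raise ValueError("fewer than 2 populations survive the size filter")
    enc = _encode_pairwise(matrix)
    k = len(surviving)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = mean_p_distance(matrix, surviving[i], surviving[j], _enc=enc)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(surviving, vals)


def diversity_summary(
    matrix: AlignedMatrix, population: str | None = None
) -> dict:
    """n, distinct haplotypes, segregating sites, Hd and Pi for one group."""
    m = matrix if population is None else matrix.subset([population])
    cols = usable_columns(m)
    counts = haplotype_counts(m, cols)
    return {
        "population": population or "ALL",
        "n": m.n,
        "k_hap": len(counts),
        "S": segregating_sites(m, cols),
        "Hd": haplotype_diversity(m, cols) if m.n >= 2 else float("nan"),
        "Pi": nucleotide_diversity(m, cols) if m.n >= 2 and len(cols) else float("nan"),
        "usable_sites": int(len(cols)),
    }


def diversity_table(matrix: AlignedMatrix) -> pd.DataFrame:
    rows = [diversity_summary(matrix)]
    for pop in sorted(set(matrix.populations)):
        rows.append(diversity_summary(matrix, pop))
    return pd.DataFrame(rows)
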