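"""Pairwise haplotype sharing between populations.

Two samples share a haplotype iff their masked variant sets, restricted to a
common comparison window, are identical (N is a literal character: masking
happens before sharing, and wildcard matching would break transitivity of the
equality). The headline statistic for a population pair is the symmetric
sharing ratio: the mean of |A∩B|/|A| and |A∩B|/|B| over distinct haplotypes.
Both directional ratios are always reported alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .coords import CoordinateWindow, EURASIAN_546
from .variants import (
    HaplotypeProfile,
    format_variants,
    mask_heteroplasmies,
    restrict_window,
)

ORIGIN_FILTERS = ("all", "EAs", "WEu")


def haplotype_key(profile: HaplotypeProfile, window: CoordinateWindow) -> str:
    """Canonical, order-insensitive key of a masked, window-restricted profile."""
    p = restrict_window(mask_heteroplasmies(profile), window)
    return format_variants(p.variants)


def haplotype_sets(
    profiles: Sequence[HaplotypeProfile],
    window: CoordinateWindow = EURASIAN_546,
    origin_filter: str = "all",
    origins: Mapping[str, str] | None = None,
) -> dict[str, set[str]]:
    """Distinct haplotype keys per population, optionally origin-filtered.

    *origins* maps sample_id -> origin class ("EAs"/"WEu"); required whenever
    *origin_filter* is not "all".
    """
    if origin_filter not in ORIGIN_FILTERS:
        raise ValueError(f"origin_filter must be one of {ORIGIN_FILTERS}")
    sets: dict[str, set[str]] = {}
    for pr in profiles:
        if origin_filter != "all":
            if origins is None or pr.sample_id not in origins:
                raise ValueError(
                    f"origin filter {origin_filter!r} needs a classification "
                    f"for sample {pr.sample_id!r}"
                )
            if origins[pr.sample_id] != origin_filter:
                continue
        sets.setdefault(pr.population, set()).add(haplotype_key(pr, window))
    return sets


class SharingRatio(NamedTuple):
    shared: int
    ratio_ab: float
    ratio_ba: float
    ratio_sym: float


def sharing_ratio(
    sets: Mapping[str, set[str]], a: str, b: str
) -> SharingRatio:
    """Shared count and the three sharing ratios for a population pair."""
    try:
        A, B = sets[a], sets[b]
    except KeyError as exc:
        raise ValueError(f"unknown population {exc.args[0]!r}") from None
    if not A or not B:
        raise ValueError(f"empty haplotype set for {a!r} or {b!r}")
    shared = len(A & B)
    r_ab = shared / len(A)
    r_ba = shared / len(B)
    return SharingRatio(shared, r_ab, r_ba, (r_ab + r_ba) / 2)


@dataclass
class SharingMatrix:
    labels: list[str]
    shared_counts: np.ndarray
    ratio: np.ndarray
    origin_filter: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ratio, index=self.labels, columns=self.labels)


def sharing_matrix(
    sets: Mapping[str, set[str]], origin_filter: str = "all"
) -> SharingMatrix:
    labels = sorted(sets)
    if len(labels) < 2:
        raise ValueError("sharing matrix needs at least 2 populations")
    k = len(labels)
    shared = np.zeros((k, k), dtype=int)
    ratio = np.zeros((k, k))
    for i, a in enumerate(labels):
        shared[i, i] = len(sets[a])
        ratio[i, i] = 1.0
        for j in range(i + 1, k):
            r = sharing_ratio(sets, a, labels[j])
            shared[i, j] = shared[j, i] = r.shared
            ratio[i, j] = ratio[j, i] = r.ratio_sym
    return SharingMatrix(labels, shared, ratio, origin_filter)


def sharing_long_table(
    sets: Mapping[str, set[str]], origin_filter: str = "all"
) -> pd.DataFrame:
    """Long-format report with all ratio variants, one row per pair."""
    labels = sorted(sets)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            r = sharing_ratio(sets, a, b)
            rows.append(
                {
                    "pop_a": a,
                    "pop_b": b,
                    "origin_filter": origin_filter,
                    "shared": r.shared,
                    "n_hap_a": len(sets[a]),
                    "n_hap_b": len(sets[b]),
                    "ratio_ab": r.ratio_ab,
                    "ratio_ba": r.ratio_ba,
                    "ratio_sym": r.ratio_sym,
                }
            )
    return pd.DataFrame(rows)
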