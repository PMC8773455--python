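"""Synthetic data with known truth for every pipeline stage.

Modern cohorts are drawn from configured per-population haplogroup-frequency
vectors over the packaged motif tree's leaves: each sample's sequence is the
reference window edited by its haplogroup's cumulative motif, plus
Poisson-distributed private substitutions at uniform non-motif positions and,
optionally, one heteroplasmic (two-base IUPAC) position. Ancient metadata
tables realise per-lineage trajectory specs (a dated record inside the
longitude band of interest, an optional older precursor to the west), so the
arrival-tracing stage has exact truth statuses.

The default demo cohort mirrors the shape of the Mongolian study design:
20 provinces plus an "unspecified" group totalling 2,420 samples, an
eastern-Asian-dominated gene pool (~78%) with the western-Eurasian share
enriched in the westernmost provinces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calling import reconstruct_sequence
from .coords import CONTROL_REGION, CoordinateWindow, ReferenceSequence
from .haplotree import MotifTree
from .variants import (
    SUBSTITUTION,
    HaplotypeProfile,
    IUPAC_PAIR,
    VariantCall,
    format_variants,
    mask_heteroplasmies,
)

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n: int
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulationError(f"{self.name}: n must be >= 1")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"{self.name}: frequency vector sums to {total}, not 1"
            )


@dataclass(frozen=True)
class SimConfig:
    seed: int
    populations: list[PopulationSpec]
    private_rate: float = 0.0
    heteroplasmy_prob: float = 0.0
    window: CoordinateWindow = CONTROL_REGION

    def __post_init__(self) -> None:
        if self.private_rate < 0 or not 0 <= self.heteroplasmy_prob <= 1:
            raise SimulationError("rates must be non-negative (prob in [0,1])")


def _check_leaves(config: SimConfig, tree: MotifTree) -> None:
    leaves = set(tree.leaves())
    for pop in config.populations:
        bad = set(pop.frequencies) - leaves
        if bad:
            raise SimulationError(
                f"{pop.name}: frequency entries are not tree leaves: {sorted(bad)}"
            )


def _private_substitutions(
    rng: np.random.Generator,
    k: int,
    free_positions: np.ndarray,
    reference: ReferenceSequence,
) -> list[VariantCall]:
    if k == 0:
        return []
    chosen = rng.choice(free_positions, size=min(k, len(free_positions)), replace=False)
    calls = []
    for pos in chosen:
        ref = reference.base_at(int(pos))
        alts = [b for b in _BASES if b != ref]
        alt = alts[int(rng.integers(0, len(alts)))]
        calls.append(VariantCall(int(pos), SUBSTITUTION, alt))
    return calls


def _heteroplasmise(
    rng: np.random.Generator,
    variants: list[VariantCall],
    reference: ReferenceSequence,
) -> list[VariantCall]:
    """Turn one substitution into a two-base IUPAC mix of derived + reference."""
    subs = [
        i
        for i, v in enumerate(variants)
        if v.kind == SUBSTITUTION and v.derived_base in _BASES
    ]
    if not subs:
        return variants
    i = subs[int(rng.integers(0, len(subs)))]
    v = variants[i]
    ref = reference.base_at(v.position)
    code = IUPAC_PAIR.get(frozenset((v.derived_base, ref)))
    if code is None:  # pragma: no cover - derived == ref cannot happen
        return variants
    out = list(variants)
    out[i] = replace(v, derived_base=code)
    return out


def simulate_modern(
    config: SimConfig,
    tree: MotifTree,
    reference: ReferenceSequence,
):
    """Generate (records, truth) for a modern control-region cohort.

    *records* is a list of (sample_id, sequence, population); *truth* a
    DataFrame with the generating haplogroup, the planted variant string and
    the masked haplotype key of every sample. Fully reproducible from
    ``config.seed``.
    """
    _check_leaves(config, tree)
    rng = np.random.default_rng(config.seed)
    window = config.window
    window_positions = np.array(window.positions())
    records: list[tuple[str, str, str]] = []
    truth_rows = []
    for pop in config.populations:
        leaf_names = sorted(pop.frequencies)
        probs = np.array([pop.frequencies[l] for l in leaf_names])
        probs = probs / probs.sum()
        draws = rng.choice(len(leaf_names), size=pop.n, p=probs)
        for i, d in enumerate(draws):
            hg = leaf_names[int(d)]
            motif = sorted(tree.cumulative_motif(hg, window))
            motif_pos = {v.position for v in motif}
            free = window_positions[
                ~np.isin(window_positions, sorted(motif_pos))
            ]
            k = int(rng.poisson(config.private_rate)) if config.private_rate else 0
            privates = _private_substitutions(rng, k, free, reference)
            variants = motif + privates
            if config.heteroplasmy_prob and rng.random() < config.heteroplasmy_prob:
                variants = _heteroplasmise(rng, variants, reference)
            sid = f"{pop.name}_{i:05d}"
            profile = HaplotypeProfile(sid, pop.name, window, frozenset(variants))
            seq = reconstruct_sequence(profile, reference)
            records.append((sid, seq, pop.name))
            truth_rows.append(
                {
                    "sample_id": sid,
                    "population": pop.name,
                    "haplogroup": hg,
                    "planted_variants": format_variants(variants),
                    "haplotype_key": format_variants(
                        mask_heteroplasmies(profile).variants
                    ),
                }
            )
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# planted haplotype sharing between a population pair


def simulate_shared_pair(
    tree: MotifTree,
    reference: ReferenceSequence,
    seed: int,
    n_hap: int = 120,
    shared_fraction: float = 0.3,
    window: CoordinateWindow = CONTROL_REGION,
    names: tuple[str, str] = ("popA", "popB"),
):
    """Two populations of *n_hap* distinct haplotypes each, with an expected
    fraction *shared_fraction* of B's haplotypes copied from A.

    Every non-copied haplotype carries a unique pair of private substitutions,
    so distinctness (and hence the planted sharing count) is exact. Returns
    (profiles, true_shared_count).
    """
    rng = np.random.default_rng(seed)
    leaves = sorted(tree.leaves())
    motif_pos = set()
    for leaf in leaves:
        motif_pos |= {v.position for v in tree.cumulative_motif(leaf, window)}
    pool = [p for p in window.positions() if p not in motif_pos]
    rng.shuffle(pool)
    if len(pool) < 2 * (2 * n_hap):
        raise SimulationError("window too small for the requested n_hap")
    pair_iter = iter(range(0, 2 * 2 * n_hap, 2))

    def new_haplotype() -> frozenset[VariantCall]:
        leaf = leaves[int(rng.integers(0, len(leaves)))]
        base = set(tree.cumulative_motif(leaf, window))
        start = next(pair_iter)
        for pos in pool[start : start + 2]:
            ref = reference.base_at(pos)
            alt = "A" if ref != "A" else "G"
            base.add(VariantCall(pos, SUBSTITUTION, alt))
        return frozenset(base)

    a_haps = [new_haplotype() for _ in range(n_hap)]
    copy_mask = rng.random(n_hap) < shared_fraction
    donors = rng.choice(n_hap, size=int(copy_mask.sum()), replace=False)
    b_haps = []
    di = iter(donors)
    for copy in copy_mask:
        b_haps.append(a_haps[int(next(di))] if copy else new_haplotype())
    profiles = []
    for pop_name, haps in zip(names, (a_haps, b_haps)):
        for i, h in enumerate(haps):
            profiles.append(
                HaplotypeProfile(f"{pop_name}_{i:04d}", pop_name, window, h)
            )
    return profiles, int(copy_mask.sum())


# ---------------------------------------------------------------------------
# ancient trajectories


@dataclass(frozen=True)
class LineageTrajectory:
    """One lineage's planted spatiotemporal history.

    ``band_date``/``band_lon`` place the earliest record inside the band of
    interest (None = lineage absent there); ``precursor_date``/``precursor_lon``
    optionally place an older record to the west.
    """

    lineage: str
    band_date: float | None = None
    band_lon: float | None = None
    precursor_date: float | None = None
    precursor_lon: float | None = None
    record_label: str | None = None  # haplogroup label on the records


def simulate_ancient(
    trajectories: list[LineageTrajectory],
    band_lon_range: tuple[float, float] = (85.0, 125.0),
    cutoff_ce: float = -1000.0,
    offset_range: tuple[float, float] = (20.0, 40.0),
):
    """Realise trajectory specs as ancient records plus a truth table."""
    from .ancient import AncientRecord  # local import to avoid cycle

    lo, hi = band_lon_range
    if lo >= hi:
        raise SimulationError("band_lon_range must be increasing")
    records = []
    truth_rows = []
    for tr in trajectories:
        label = tr.record_label or tr.lineage
        if tr.band_date is not None:
            if tr.band_lon is None or not lo <= tr.band_lon <= hi:
                raise SimulationError(
                    f"{tr.lineage}: band_lon must lie in {band_lon_range}"
                )
            records.append(
                AncientRecord(
                    f"{tr.lineage}_band",
                    label,
                    tr.band_date,
                    tr.band_lon,
                    47.0,
                    "band_site",
                )
            )
        if tr.precursor_date is not None:
            if tr.precursor_lon is None or (
                tr.band_lon is not None and tr.precursor_lon >= tr.band_lon
            ):
                raise SimulationError(
                    f"{tr.lineage}: precursor must lie west of the band record"
                )
            records.append(
                AncientRecord(
                    f"{tr.lineage}_precursor",
                    label,
                    tr.precursor_date,
                    tr.precursor_lon,
                    45.0,
                    "western_site",
                )
            )
        if tr.band_date is None:
            status = "absent_in_band"
            consistent = False
        else:
            status = (
                "pre_cutoff_presence"
                if tr.band_date <= cutoff_ce
                else "post_cutoff_arrival"
            )
            offset = (
                tr.band_lon - tr.precursor_lon
                if tr.precursor_lon is not None
                else None
            )
            consistent = bool(
                status == "post_cutoff_arrival"
                and offset is not None
                and offset_range[0] <= offset <= offset_range[1]
                and tr.precursor_date < tr.band_date
            )
        truth_rows.append(
            {
                "lineage": tr.lineage,
                "status": status,
                "route_consistent": consistent,
            }
        )
    return records, pd.DataFrame(truth_rows)


def narrative_trajectories() -> list[LineageTrajectory]:
    """The packaged synthetic arrival narrative.

    Thirteen western-Eurasian sub-lineages arrive in the band after 1000 BCE;
    six of them (traced at the T2g level for the T clade) follow a
    trade-route-consistent trajectory: an older precursor 20-40 degrees of
    longitude to the west. Five further lineages are planted as present
    before the cutoff.
    """
    t: list[LineageTrajectory] = []
    # route-consistent arrivals (~2,500 years ago, precursor 30 deg west)
    for ln in ("H5a1", "J1b2", "U2e1b", "U4b1a1a1", "U4b1a4"):
        t.append(LineageTrajectory(ln, -500.0, 100.0, -800.0, 70.0))
    # T traced at T2g via a T2g1-labelled pair; T2g1a itself arrives later
    # from a far-western precursor (offset 55 > 40: not route-consistent)
    t.append(LineageTrajectory("T2g", -500.0, 100.0, -800.0, 70.0, record_label="T2g1"))
    t.append(LineageTrajectory("T2g1a", 300.0, 100.0, -350.0, 45.0))
    # later, non-route-consistent arrivals
    t.append(LineageTrajectory("I1c", -400.0, 95.0, -900.0, 40.0))
    t.append(LineageTrajectory("J1b1b1", 400.0, 105.0, -200.0, 50.0))
    t.append(LineageTrajectory("J1d6", -300.0, 110.0))
    t.append(LineageTrajectory("U2e1a1", 500.0, 98.0, 100.0, 48.0))
    t.append(LineageTrajectory("U4d2", -600.0, 92.0, -700.0, 30.0))
    t.append(LineageTrajectory("U5b1c2", -200.0, 102.0))
    t.append(LineageTrajectory("U8b1a1", -100.0, 96.0, -2000.0, 25.0))
    # lineages already present before 1000 BCE
    t.append(LineageTrajectory("U5a1", -2800.0, 101.0, -3300.0, 60.0))
    t.append(LineageTrajectory("H1b", -2000.0, 99.0))
    t.append(LineageTrajectory("X2", -1500.0, 93.0, -2500.0, 35.0))
    t.append(LineageTrajectory("W1", -1200.0, 104.0))
    t.append(LineageTrajectory("K", -1100.0, 108.0, -4000.0, 20.0))
    return t


# ---------------------------------------------------------------------------
# demo cohort shaped like the Mongolian study design

PROVINCE_SIZES = {
    "Arkhangai": 4,
    "Bayankhongor": 2,
    "Bayan-Olgii": 216,
    "Bulgan": 5,
    "Darkhan-Uul": 1,
    "Dornod": 370,
    "Dornogovi": 26,
    "Dundgovi": 1,
    "Govi-Altai": 8,
    "Khentii": 132,
    "Khovd": 429,
    "Khovsgol": 307,
    "Omnogovi": 2,
    "Ovorkhangai": 8,
    "Selenge": 4,
    "Sukhbaatar": 246,
    "Tov": 10,
    "Ulaanbaatar": 2,
    "Uvs": 132,
    "Zavkhan": 167,
    "unspecified": 348,
}

#: provinces below 30 samples are pooled into three geographic macro-areas
PROVINCE_MACRO_AREAS = {
    "Bayankhongor": "Gobi Desert",
    "Dornogovi": "Gobi Desert",
    "Dundgovi": "Gobi Desert",
    "Govi-Altai": "Gobi Desert",
    "Omnogovi": "Gobi Desert",
    "Arkhangai": "Khangai Mountains",
    "Ovorkhangai": "Khangai Mountains",
    "Bulgan": "Near Ulaanbaatar",
    "Darkhan-Uul": "Near Ulaanbaatar",
    "Selenge": "Near Ulaanbaatar",
    "Tov": "Near Ulaanbaatar",
    "Ulaanbaatar": "Near Ulaanbaatar",
}

#: western-Eurasian share per province (westernmost provinces enriched;
#: cohort-wide share ~0.22)
_WEU_SHARE = {
    "Bayan-Olgii": 0.50,
    "Khovd": 0.33,
    "Uvs": 0.33,
    "Zavkhan": 0.28,
    "Govi-Altai": 0.28,
    "Bayankhongor": 0.25,
    "Arkhangai": 0.20,
    "Ovorkhangai": 0.20,
    "Khovsgol": 0.18,
    "Bulgan": 0.18,
    "Tov": 0.18,
    "Ulaanbaatar": 0.22,
    "Darkhan-Uul": 0.18,
    "Selenge": 0.18,
    "Dundgovi": 0.15,
    "Omnogovi": 0.15,
    "Dornogovi": 0.15,
    "Khentii": 0.13,
    "Sukhbaatar": 0.12,
    "Dornod": 0.11,
    "unspecified": 0.20,
}

_EAS_WEIGHTS = {
    "C4a": 0.24,
    "D4b": 0.20,
    "D5": 0.04,
    "G2a": 0.06,
    "B4": 0.05,
    "B5": 0.03,
    "A4": 0.07,
    "M7b": 0.04,
    "M7c": 0.02,
    "Z": 0.03,
    "M9a": 0.03,
    "N9a": 0.04,
    "Y": 0.03,
    "F1": 0.06,
    "M10": 0.02,
    "M11": 0.01,
    "R11": 0.01,
    "L3e": 0.01,
}

_WEU_WEIGHTS = {
    "H1b": 0.11,
    "H1c": 0.08,
    "H1j": 0.05,
    "H5a1": 0.06,
    "HV13b1": 0.04,
    "V": 0.03,
    "J1b1b1": 0.05,
    "J1b2": 0.05,
    "J1d6": 0.03,
    "T2g1a": 0.07,
    "U2e1a1": 0.04,
    "U2e1b": 0.04,
    "U4b1a1a1": 0.05,
    "U4b1a4": 0.05,
    "U4d2": 0.04,
    "U5a1": 0.08,
    "U5b1c2": 0.04,
    "U8b1a1": 0.03,
    "K": 0.03,
    "N1a": 0.02,
    "I1c": 0.03,
    "W1": 0.04,
    "X2": 0.04,
}


def demo_config(
    seed: int,
    private_rate: float = 1.0,
    heteroplasmy_prob: float = 0.02,
    window: CoordinateWindow = CONTROL_REGION,
    scale: float = 1.0,
) -> SimConfig:
    """Study-shaped cohort: 21 groups, 2,420 samples (scalable for demos)."""
    eas_total = sum(_EAS_WEIGHTS.values())
    weu_total = sum(_WEU_WEIGHTS.values())
    pops = []
    for name, n in PROVINCE_SIZES.items():
        w = _WEU_SHARE[name]
        freqs = {k: (1 - w) * v / eas_total for k, v in _EAS_WEIGHTS.items()}
        freqs.update({k: w * v / weu_total for k, v in _WEU_WEIGHTS.items()})
        total = sum(freqs.values())
        freqs = {k: v / total for k, v in freqs.items()}
        pops.append(PopulationSpec(name, max(1, round(n * scale)), freqs))
    return SimConfig(
        seed=seed,
        populations=pops,
        private_rate=private_rate,
        heteroplasmy_prob=heteroplasmy_prob,
        window=window,
    )


def apply_province_grouping(
    population: str, sizes: dict[str, int] | None = None, min_n: int = 30
) -> str:
    """Pool small provinces into their geographic macro-area label."""
    sizes = sizes or PROVINCE_SIZES
    if sizes.get(population, min_n) < min_n:
        return PROVINCE_MACRO_AREAS.get(population, population)
    return population
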