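"""rCRS-relative variant calls and per-sample haplotype profiles.

Variants use the forensic/EMPOP text notation: ``16189C`` for a substitution,
``16193.1C`` for the first inserted base after np 16193, ``249del`` for a
deletion. Heteroplasmic positions carry an IUPAC two-base ambiguity code and
are masked to ``N`` before any haplotype-level comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .coords import MT_LENGTH, CoordinateWindow

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
#: two-base ambiguity code for each unordered base pair
IUPAC_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

_VARIANT_RE = re.compile(
    r"^(?P<pos>\d{1,5})"
    r"(?:"
    r"(?P<del>DEL)"
    r"|\.(?P<idx>\d+)(?P<insbase>[ACGTN])"
    r"|(?P<base>[ACGTNRYSWKMBDHV])"
    r")$"
)


class VariantFormatError(ValueError):
    """Raised for unparseable variant tokens."""


@dataclass(frozen=True, order=True)
class VariantCall:
    position: int
    kind: str
    derived_base: str = ""
    insertion_index: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise ValueError(f"position {self.position} outside rCRS")
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise ValueError(f"bad variant kind {self.kind!r}")
        if self.kind == DELETION and self.derived_base:
            raise ValueError("deletions carry no derived base")
        if self.kind == INSERTION and self.insertion_index < 1:
            raise ValueError("insertion_index must be >= 1")
        if self.kind != INSERTION and self.insertion_index:
            raise ValueError("insertion_index only valid for insertions")
        if self.kind != DELETION and not self.derived_base:
            raise ValueError("substitutions/insertions need a derived base")

    @property
    def key(self) -> tuple[int, str, int]:
        """Identity of the varied site: (position, kind, insertion_index)."""
        return (self.position, self.kind, self.insertion_index)

    def __str__(self) -> str:
        if self.kind == DELETION:
            return f"{self.position}del"
        if self.kind == INSERTION:
            return f"{self.position}.{self.insertion_index}{self.derived_base}"
        return f"{self.position}{self.derived_base}"


def parse_variant(token: str) -> VariantCall:
    m = _VARIANT_RE.match(token.strip().upper())
    if not m:
        raise VariantFormatError(f"unparseable variant token {token!r}")
    pos = int(m.group("pos"))
    if m.group("del"):
        return VariantCall(pos, DELETION)
    if m.group("idx"):
        return VariantCall(pos, INSERTION, m.group("insbase"), int(m.group("idx")))
    return VariantCall(pos, SUBSTITUTION, m.group("base"))


def format_variants(variants) -> str:
    """Canonical space-separated text form, sorted by site."""
    return " ".join(str(v) for v in sorted(variants))


@dataclass(frozen=True)
class HaplotypeProfile:
    """One sample's rCRS-relative variant set over a coverage window."""

    sample_id: str
    population: str
    window: CoordinateWindow
    variants: frozenset[VariantCall] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", frozenset(self.variants))
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError(
                f"{self.sample_id}: duplicate variant site in profile"
            )
        for v in self.variants:
            if v.position not in self.window:
                raise ValueError(
                    f"{self.sample_id}: variant {v} outside window "
                    f"{self.window.start}..{self.window.end}"
                )

    def sorted_variants(self) -> list[VariantCall]:
        return sorted(self.variants)


def mask_heteroplasmies(profile: HaplotypeProfile) -> HaplotypeProfile:
    """Replace IUPAC ambiguity codes (heteroplasmies) with N.

    Idempotent; calls whose derived base is already A/C/G/T/N pass through.
    """
    masked = frozenset(
        replace(v, derived_base="N")
        if v.derived_base in IUPAC_AMBIGUOUS
        else v
        for v in profile.variants
    )
    return replace(profile, variants=masked)


def restrict_window(
    profile: HaplotypeProfile, window: CoordinateWindow
) -> HaplotypeProfile:
    """Restrict a profile to a nested sub-window, dropping outside variants."""
    if not profile.window.contains_window(window):
        raise ValueError(
            f"window {window.start}..{window.end} not nested in profile "
            f"window {profile.window.start}..{profile.window.end}"
        )
    kept = frozenset(v for v in profile.variants if v.position in window)
    return replace(profile, window=window, variants=kept)
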