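"""Motif trees and haplogroup classification.

A motif tree is a rooted tree of haplogroup nodes; each branch carries the
mutations (rCRS-relative) expected to have occurred on it. The cumulative
motif of a node is the sequential application of branch motifs along the root
path, with back mutations ("!" tokens) cancelling earlier expectations at the
same position. Classification scores each node against an observed profile
and returns the best-supported haplogroup together with the evidence split
into matched / missing-expected / private variants.

The classifier is intentionally window-aware: for control-region-only data
only the expected mutations that fall inside the profile's coverage window
enter the score, so coding-region motif content neither helps nor hurts.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .coords import CoordinateWindow
from .variants import (
    HaplotypeProfile,
    VariantCall,
    VariantFormatError,
    parse_variant,
)


class TreeFormatError(ValueError):
    """Malformed motif-tree file."""


class ClassificationError(ValueError):
    pass


@dataclass
class MotifNode:
    name: str
    parent: str | None
    motif: list[VariantCall] = field(default_factory=list)
    #: positions whose earlier expectation this branch reverts
    reversions: list[int] = field(default_factory=list)
    depth: int = 0
    children: list[str] = field(default_factory=list)


class MotifTree:
    def __init__(self, nodes: dict[str, MotifNode], root: str):
        self.nodes = nodes
        self.root = root
        self._cumulative: dict[str, dict] = {}

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def node(self, name: str) -> MotifNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise ClassificationError(f"unknown haplogroup {name!r}") from None

    def root_path(self, name: str) -> list[str]:
        path = []
        cur: str | None = name
        while cur is not None:
            path.append(cur)
            cur = self.node(cur).parent
        return list(reversed(path))

    def is_descendant(self, name: str, ancestor: str) -> bool:
        """True if *name* equals *ancestor* or lies below it."""
        return ancestor in self.root_path(name)

    def leaves(self) -> list[str]:
        return [n for n, nd in self.nodes.items() if not nd.children]

    def cumulative_motif(
        self, name: str, window: CoordinateWindow | None = None
    ) -> set[VariantCall]:
        """Expected variant set of a node, optionally window-restricted."""
        if name not in self._cumulative:
            state: dict[tuple, VariantCall] = {}
            for step in self.root_path(name):
                nd = self.nodes[step]
                for pos in nd.reversions:
                    for key in [k for k in state if k[0] == pos]:
                        del state[key]
                for v in nd.motif:
                    state[v.key] = v
            self._cumulative[name] = dict(state)
        state = self._cumulative[name]
        if window is None:
            return set(state.values())
        return {v for v in state.values() if v.position in window}


def _parse_motif_tokens(tokens: Iterable[str], line_no: int):
    motif: list[VariantCall] = []
    reversions: list[int] = []
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            continue
        bangs = len(tok) - len(tok.rstrip("!"))
        core = tok.rstrip("!")
        try:
            if bangs % 2 == 1:
                # back mutation: accept bare "16189!" or full "16189C!"
                pos = int(core) if core.isdigit() else parse_variant(core).position
                reversions.append(pos)
            else:
                motif.append(parse_variant(core))
        except (ValueError, VariantFormatError) as exc:
            raise TreeFormatError(
                f"line {line_no}: bad motif token {tok!r}"
            ) from exc
    return motif, reversions


def load_motif_tree(stream) -> MotifTree:
    """Parse a motif-tree TSV: node_name, parent_name, motif tokens.

    The root row has an empty parent field (or "-") and an empty motif.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    nodes: dict[str, MotifNode] = {}
    root: str | None = None
    for ln, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TreeFormatError(f"line {ln}: expected >=2 tab-separated fields")
        name, parent = parts[0].strip(), parts[1].strip()
        if name in nodes:
            raise TreeFormatError(f"line {ln}: duplicate node name {name!r}")
        motif, reversions = _parse_motif_tokens(
            parts[2].split() if len(parts) > 2 else [], ln
        )
        if parent in ("", "-"):
            if root is not None:
                raise TreeFormatError(f"line {ln}: second root {name!r}")
            if motif or reversions:
                raise TreeFormatError(f"line {ln}: root must have empty motif")
            root = name
            parent_ref = None
        else:
            parent_ref = parent
        nodes[name] = MotifNode(name, parent_ref, motif, reversions)
    if root is None:
        raise TreeFormatError("no root node found")
    for name, nd in nodes.items():
        if nd.parent is not None:
            if nd.parent not in nodes:
                raise TreeFormatError(
                    f"node {name!r} references missing parent {nd.parent!r}"
                )
            nodes[nd.parent].children.append(name)
    # depths + cycle check
    for name, nd in nodes.items():
        seen = set()
        cur, d = name, 0
        while nodes[cur].parent is not None:
            if cur in seen:
                raise TreeFormatError(f"cycle through node {cur!r}")
            seen.add(cur)
            cur = nodes[cur].parent
            d += 1
        nd.depth = d
    return MotifTree(nodes, root)


@dataclass(frozen=True)
class MacroGroupTable:
    """Longest-prefix rules mapping haplogroup names to macro labels/origins."""

    prefix_to_macro: dict[str, str]
    macro_to_origin: dict[str, str]

    def macro_group(self, haplogroup: str) -> str:
        best = None
        for prefix, macro in self.prefix_to_macro.items():
            if haplogroup.startswith(prefix):
                if best is None or len(prefix) > len(best[0]):
                    best = (prefix, macro)
        if best is None:
            raise ClassificationError(
                f"haplogroup {haplogroup!r} matches no macro-group rule"
            )
        return best[1]

    def origin_of(self, macro: str) -> str:
        try:
            return self.macro_to_origin[macro]
        except KeyError:
            raise ClassificationError(f"unknown macro-haplogroup {macro!r}") from None


def load_macro_table(stream) -> MacroGroupTable:
    """TSV with columns prefix, macro, origin (one row per prefix rule)."""
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    p2m: dict[str, str] = {}
    m2o: dict[str, str] = {}
    for ln, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("prefix\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise TreeFormatError(f"macro table line {ln}: expected 3 columns")
        prefix, macro, origin = (p.strip() for p in parts)
        if origin not in ("EAs", "WEu"):
            raise TreeFormatError(f"macro table line {ln}: bad origin {origin!r}")
        if prefix in p2m:
            raise TreeFormatError(f"macro table line {ln}: duplicate prefix")
        p2m[prefix] = macro
        if macro in m2o and m2o[macro] != origin:
            raise TreeFormatError(
                f"macro table line {ln}: conflicting origin for {macro!r}"
            )
        m2o[macro] = origin
    return MacroGroupTable(p2m, m2o)


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    haplogroup: str
    score: float
    matched: frozenset[VariantCall]
    unmatched_expected: frozenset[VariantCall]
    private: frozenset[VariantCall]


def _score_node(
    expected: set[VariantCall],
    observed: frozenset[VariantCall],
    missing_weight: float,
):
    exp_by_key = {v.key: v for v in expected}
    matched, private = [], []
    matched_keys = set()
    for ov in observed:
        ev = exp_by_key.get(ov.key)
        if ev is not None and (ov.derived_base == ev.derived_base or ov.derived_base == "N"):
            matched.append(ov)
            matched_keys.add(ov.key)
        else:
            private.append(ov)
    unmatched = [v for v in expected if v.key not in matched_keys]
    score = (len(matched) - missing_weight * len(unmatched)) / (
        len(matched) + len(private) + 1e-9
    )
    return score, matched, unmatched, private


def classify(
    profile: HaplotypeProfile,
    tree: MotifTree,
    missing_weight: float = 0.5,
) -> ClassificationResult:
    """Assign the best-scoring haplogroup to a (masked) profile.

    Score of a node = (matched - w*missing_expected_in_window) /
    (matched + private + 1e-9); observed N substitutions match any expected
    base at their position. Ties go to the deeper node, then the
    lexicographically smaller name.
    """
    if not tree.nodes:
        raise ClassificationError("empty motif tree")
    best = None
    for name in tree.nodes:
        expected = tree.cumulative_motif(name, profile.window)
        score, matched, unmatched, private = _score_node(
            expected, profile.variants, missing_weight
        )
        key = (score, tree.nodes[name].depth, _NegStr(name))
        if best is None or key > best[0]:
            best = (key, name, score, matched, unmatched, private)
    _, name, score, matched, unmatched, private = best
    return ClassificationResult(
        sample_id=profile.sample_id,
        haplogroup=name,
        score=score,
        matched=frozenset(matched),
        unmatched_expected=frozenset(unmatched),
        private=frozenset(private),
    )


class _NegStr(str):
    """Reverses string comparison so max() prefers the smaller name."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def load_packaged_tree() -> MotifTree:
    """The packaged synthetic PhyloTree-style subset (see data/README note)."""
    with resources.files("mtlineage.data").joinpath("minitree.tsv").open() as fh:
        return load_motif_tree(fh)


def load_packaged_macro_table() -> MacroGroupTable:
    with resources.files("mtlineage.data").joinpath("macrogroups.tsv").open() as fh:
        return load_macro_table(fh)
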