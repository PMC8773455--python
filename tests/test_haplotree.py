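"""Motif-tree parsing, cumulative motifs and haplogroup classification."""

import numpy as np
import pytest

from mtlineage.coords import CONTROL_REGION, CoordinateWindow
from mtlineage.haplotree import (
    ClassificationError,
    TreeFormatError,
    classify,
    load_motif_tree,
)
from mtlineage.variants import HaplotypeProfile, format_variants, parse_variant

FULL = CoordinateWindow(1, 16569)

TOY = (
    "root\t-\t\n"
    "H\troot\t7028C 2706G\n"
    "H1\tH\t3010A\n"
)


class TestLoadTree:
    def test_toy_tree(self):
        t = load_motif_tree(TOY)
        assert set(t.nodes) == {"root", "H", "H1"}
        assert t.nodes["H1"].depth == 2

    def test_missing_parent_errors(self):
        with pytest.raises(TreeFormatError, match="missing parent"):
            load_motif_tree("root\t-\t\nH1\tH\t3010A\n")

    def test_duplicate_name_errors(self):
        with pytest.raises(TreeFormatError, match="duplicate"):
            load_motif_tree("root\t-\t\nA\troot\t73G\nA\troot\t74G\n")

    def test_bad_token_reports_line(self):
        with pytest.raises(TreeFormatError, match="line 2"):
            load_motif_tree("root\t-\t\nA\troot\t73Q\n")

    def test_packaged_tree_covers_both_origins(self, tree, macro_table):
        origins = {
            macro_table.origin_of(macro_table.macro_group(leaf))
            for leaf in tree.leaves()
        }
        assert origins == {"EAs", "WEu"}


class TestCumulativeMotif:
    def test_root_is_empty(self, tree):
        assert tree.cumulative_motif("rCRS") == set()

    def test_union_along_path(self):
        t = load_motif_tree(TOY)
        got = t.cumulative_motif("H1", FULL)
        assert got == {
            parse_variant("7028C"),
            parse_variant("2706G"),
            parse_variant("3010A"),
        }

    def test_reversion_cancels_expectation(self):
        t = load_motif_tree(
            "root\t-\t\nA\troot\t16189C 73G\nA1\tA\t16189!\nA1a\tA1\t16189C\n"
        )
        assert t.cumulative_motif("A1", FULL) == {parse_variant("73G")}
        # re-adding after a reversion restores the expectation
        assert parse_variant("16189C") in t.cumulative_motif("A1a", FULL)

    def test_reversion_matches_sequential_application_oracle(self):
        """Cumulative motifs equal a position-by-position sequential replay."""
        rng = np.random.default_rng(3)
        positions = list(range(100, 160, 5))
        for _ in range(30):
            # random chain root -> n1 -> n2 -> n3 with random add/revert steps
            lines = ["root\t-\t"]
            steps = []
            parent = "root"
            for name in ("n1", "n2", "n3"):
                tokens = []
                for pos in rng.choice(positions, size=3, replace=False):
                    if rng.random() < 0.3:
                        tokens.append(f"{pos}!")
                    else:
                        tokens.append(f"{pos}{rng.choice(list('ACGT'))}")
                steps.append(tokens)
                lines.append(f"{name}\t{parent}\t{' '.join(tokens)}")
                parent = name
            t = load_motif_tree("\n".join(lines) + "\n")
            # oracle: replay tokens in order, tracking one state per position
            state = {}
            for tokens in steps:
                for tok in tokens:
                    if tok.endswith("!"):
                        state.pop(int(tok[:-1]), None)
                    else:
                        v = parse_variant(tok)
                        state[v.position] = v
            assert t.cumulative_motif("n3", FULL) == set(state.values())

    def test_unknown_node_errors(self, tree):
        with pytest.raises(ClassificationError):
            tree.cumulative_motif("NOPE")


def brute_force_classify(tree, profile, w=0.5):
    """Independent re-scoring of every node (test oracle)."""
    best = None
    for name, node in tree.nodes.items():
        expected = tree.cumulative_motif(name, profile.window)
        matched = unmatched = 0
        matched_keys = set()
        for ev in expected:
            hit = any(
                ov.key == ev.key
                and (ov.derived_base == ev.derived_base or ov.derived_base == "N")
                for ov in profile.variants
            )
            if hit:
                matched += 1
                matched_keys.add(ev.key)
            else:
                unmatched += 1
        private = sum(1 for ov in profile.variants if ov.key not in matched_keys)
        score = (matched - w * unmatched) / (matched + private + 1e-9)
        cand = (score, node.depth, name)
        if best is None or cand[0] > best[0] or (
            cand[0] == best[0]
            and (cand[1] > best[1] or (cand[1] == best[1] and cand[2] < best[2]))
        ):
            best = cand
    return best[2]


class TestClassify:
    def test_empty_profile_returns_reference_node(self, tree):
        prof = HaplotypeProfile("s", "p", CONTROL_REGION, [])
        assert classify(prof, tree).haplogroup == "rCRS"

    def test_hv13b_motif_plus_16184_16291_is_hv13b1(self, tree):
        """The postulated HV sub-branch: HV13b background plus control-region
        substitutions at nps 16184 and 16291."""
        variants = set(tree.cumulative_motif("HV13b", CONTROL_REGION))
        branch = {
            v for v in tree.nodes["HV13b1"].motif if v.position in CONTROL_REGION
        }
        assert {v.position for v in branch} == {16184, 16291}
        prof = HaplotypeProfile("s", "p", CONTROL_REGION, variants | branch)
        res = classify(prof, tree)
        assert res.haplogroup == "HV13b1"
        assert not res.unmatched_expected

    def test_u5b1c_plus_9110_transition_is_u5b1c2(self, tree):
        """A whole-molecule profile: U5b1c background plus the defining
        coding-region transition at np 9110."""
        variants = set(tree.cumulative_motif("U5b1c", FULL))
        branch = set(tree.nodes["U5b1c2"].motif)
        assert {v.position for v in branch} == {9110}
        prof = HaplotypeProfile("s", "p", FULL, variants | branch)
        assert classify(prof, tree).haplogroup == "U5b1c2"

    def test_n_call_matches_any_expected_base(self, tree):
        variants = set(tree.cumulative_motif("C4a", CONTROL_REGION))
        v0 = sorted(variants)[0]
        variants.remove(v0)
        variants.add(parse_variant(f"{v0.position}N"))
        prof = HaplotypeProfile("s", "p", CONTROL_REGION, variants)
        res = classify(prof, tree)
        assert res.haplogroup == "C4a"
        assert not res.private

    def test_matches_exhaustive_scoring_oracle_on_toy_trees(self):
        """On random <=12-node trees and random profiles the winner equals
        the argmax of an independently computed score."""
        rng = np.random.default_rng(4)
        window = CoordinateWindow(1, 400)
        for _ in range(50):
            names = [f"g{i}" for i in range(int(rng.integers(3, 12)))]
            lines = ["root\t-\t"]
            parents = ["root"]
            for name in names:
                parent = parents[int(rng.integers(0, len(parents)))]
                toks = [
                    f"{int(p)}{rng.choice(list('ACGT'))}"
                    for p in rng.choice(np.arange(1, 400, 7), size=2, replace=False)
                ]
                lines.append(f"{name}\t{parent}\t{' '.join(toks)}")
                parents.append(name)
            t = load_motif_tree("\n".join(lines) + "\n")
            obs = set()
            for p in rng.choice(np.arange(1, 400, 7), size=4, replace=False):
                obs.add(parse_variant(f"{int(p)}{rng.choice(list('ACGT'))}"))
            prof = HaplotypeProfile("s", "p", window, frozenset(obs))
            assert classify(prof, t).haplogroup == brute_force_classify(t, prof)

    def test_private_variant_does_not_change_winner(self, tree, reference):
        """Adding a non-motif variant leaves the call unchanged on the
        packaged tree."""
        rng = np.random.default_rng(5)
        positions = CONTROL_REGION.positions()
        for leaf in rng.choice(tree.leaves(), size=10, replace=False):
            motif = frozenset(tree.cumulative_motif(leaf, CONTROL_REGION))
            motif_pos = {v.position for v in motif}
            prof = HaplotypeProfile("s", "p", CONTROL_REGION, motif)
            base = classify(prof, tree).haplogroup
            pos = next(
                int(p) for p in rng.permutation(positions) if p not in motif_pos
            )
            ref = reference.base_at(pos)
            extra = parse_variant(f"{pos}{'A' if ref != 'A' else 'G'}")
            prof2 = HaplotypeProfile("s", "p", CONTROL_REGION, motif | {extra})
            assert classify(prof2, tree).haplogroup == base

    def test_empty_tree_errors(self):
        from mtlineage.haplotree import MotifTree

        with pytest.raises(ClassificationError, match="empty"):
            classify(
                HaplotypeProfile("s", "p", CONTROL_REGION, []),
                MotifTree({}, "x"),
            )


class TestMacroGrouping:
    @pytest.mark.parametrize(
        "haplogroup,macro",
        [
            ("H", "R0"),
            ("H1j", "R0"),
            ("J1b1b1", "JT"),
            ("J1b2", "JT"),
            ("C4a", "M8"),
            ("D4", "D"),
            ("M10", "M*"),
            ("R11", "R*"),
            ("L3e", "L3*"),
            ("K", "U"),
            ("Y", "N9"),
            ("V", "R0"),
        ],
    )
    def test_macro_group(self, macro_table, haplogroup, macro):
        assert macro_table.macro_group(haplogroup) == macro

    def test_longest_prefix_is_unique(self, macro_table):
        """Rule-enumeration oracle: among all matching prefixes the longest
        is unique and is the table answer."""
        for name in ("C4a", "M7b", "M10", "HV13b1", "N9a", "R0", "J1d6"):
            matches = [
                p for p in macro_table.prefix_to_macro if name.startswith(p)
            ]
            longest = max(matches, key=len)
            assert sum(len(p) == len(longest) for p in matches) == 1
            assert macro_table.macro_group(name) == macro_table.prefix_to_macro[longest]

    def test_unmatched_name_errors(self, macro_table):
        with pytest.raises(ClassificationError, match="no macro"):
            macro_table.macro_group("Q1")

    def test_origins_partition_the_18_macros(self, macro_table):
        macros = set(macro_table.prefix_to_macro.values())
        assert len(macros) == 18
        weu = {m for m in macros if macro_table.origin_of(m) == "WEu"}
        eas = macros - weu
        assert weu == {"JT", "N1", "N2", "R0", "U", "X"}
        assert all(macro_table.origin_of(m) == "EAs" for m in eas)

    def test_origin_examples(self, macro_table):
        assert macro_table.origin_of("R0") == "WEu"
        assert macro_table.origin_of(macro_table.macro_group("C")) == "EAs"
        with pytest.raises(ClassificationError):
            macro_table.origin_of("Z9")

    def test_total_on_packaged_tree(self, tree, macro_table):
        for name in tree.nodes:
            if name == "rCRS":
                continue
            macro = macro_table.macro_group(name)
            assert macro_table.origin_of(macro) in ("EAs", "WEu")
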