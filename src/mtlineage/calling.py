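"""rCRS-relative variant calling from control-region sequences.

A sample sequence is globally aligned to the reference window with a banded
edit-distance alignment (edlib); indels in the resulting path are then shifted
to the 3'-most position of their homopolymer run, the forensic reporting
convention, so e.g. one extra C in the 16184-16193 poly-C tract is always
reported as an insertion after the run's last reference C.
"""

from __future__ import annotations

import edlib

from .coords import CoordinateWindow, ReferenceSequence
from .variants import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    HaplotypeProfile,
    VariantCall,
)

#: maximum tolerated length difference between sequence and window
LENGTH_SLACK = 20


class AlignmentError(ValueError):
    """Sequence cannot be aligned to the reference window."""


def _alignment_ops(query: str, target: str, max_distance: int):
    """Global alignment as a list of (op, query_char, target_char).

    op is 'M' (match/mismatch), 'I' (base present in query only) or
    'D' (base present in target only).
    """
    res = edlib.align(query, target, mode="NW", task="path", k=max_distance)
    if res["editDistance"] < 0:
        raise AlignmentError(
            f"edit distance exceeds ceiling {max_distance}; sequence too "
            "divergent or truncated"
        )
    nice = edlib.getNiceAlignment(res, query, target)
    q_aln, t_aln = nice["query_aligned"], nice["target_aligned"]
    ops = []
    for qc, tc in zip(q_aln, t_aln):
        if qc == "-":
            ops.append(("D", "", tc))
        elif tc == "-":
            ops.append(("I", qc, ""))
        else:
            ops.append(("M", qc, tc))
    return ops


def _right_normalise(ops):
    """Shift indels 3'-wards through homopolymer runs.

    An insertion of base b immediately followed by an aligned reference base
    equal to b can be exchanged (match first, insert after) without changing
    the edit cost; likewise a deletion of a reference base equal to the next
    reference base. Iterating to a fixpoint places every indel at the
    3'-most coordinate of its run.
    """
    ops = list(ops)
    changed = True
    while changed:
        changed = False
        for i in range(len(ops) - 1):
            a, b = ops[i], ops[i + 1]
            if a[0] == "I" and b[0] == "M" and a[1] == b[2]:
                # insert b then match q~t (b==t)  ->  match b~t, insert q
                ops[i] = ("M", a[1], b[2])
                ops[i + 1] = ("I", b[1], "")
                changed = True
            elif a[0] == "D" and b[0] == "M" and a[2] == b[2]:
                # delete t then match q~t' (t==t') -> match q~t, delete t'
                ops[i] = ("M", b[1], a[2])
                ops[i + 1] = ("D", "", b[2])
                changed = True
    return ops


def ops_to_variants(ops, positions: list[int]) -> list[VariantCall]:
    """Translate alignment ops into VariantCalls on rCRS coordinates.

    *positions* maps target (reference-window) indices to rCRS positions in
    window order. Insertions are anchored at the rCRS position of the
    preceding reference base, with .1/.2/... indices.
    """
    calls: list[VariantCall] = []
    ti = 0  # index of next target base
    ins_run = 0
    for op, qc, tc in ops:
        if op == "M":
            ins_run = 0
            if qc != tc:
                calls.append(VariantCall(positions[ti], SUBSTITUTION, qc))
            ti += 1
        elif op == "D":
            ins_run = 0
            calls.append(VariantCall(positions[ti], DELETION))
            ti += 1
        else:  # insertion: anchor at previous reference position
            if ti == 0:
                # extra query bases 5' of the window are outside the
                # coverage window: trimmed, not called
                continue
            ins_run += 1
            calls.append(VariantCall(positions[ti - 1], INSERTION, qc, ins_run))
    return calls


def call_variants(
    sequence: str,
    reference: ReferenceSequence,
    window: CoordinateWindow,
    sample_id: str = "",
    population: str = "",
    max_distance: int = 60,
) -> HaplotypeProfile:
    """Align one sequence to the reference window and report its variants."""
    sequence = sequence.upper().replace("U", "T")
    target = reference.window_sequence(window)
    if abs(len(sequence) - len(target)) > LENGTH_SLACK:
        raise AlignmentError(
            f"{sample_id or 'sequence'}: length {len(sequence)} incompatible "
            f"with window length {len(target)} (±{LENGTH_SLACK})"
        )
    try:
        ops = _alignment_ops(sequence, target, max_distance)
    except AlignmentError as exc:
        raise AlignmentError(f"{sample_id or 'sequence'}: {exc}") from exc
    ops = _right_normalise(ops)
    calls = ops_to_variants(ops, window.positions())
    return HaplotypeProfile(
        sample_id=sample_id,
        population=population,
        window=window,
        variants=frozenset(calls),
    )


def reconstruct_sequence(
    profile: HaplotypeProfile, reference: ReferenceSequence
) -> str:
    """Rebuild the sample sequence over the profile window from its variants."""
    out: list[str] = []
    variants = sorted(profile.variants)
    by_pos: dict[int, dict] = {}
    for v in variants:
        slot = by_pos.setdefault(v.position, {"sub": None, "del": False, "ins": []})
        if v.kind == SUBSTITUTION:
            slot["sub"] = v.derived_base
        elif v.kind == DELETION:
            slot["del"] = True
        else:
            slot["ins"].append(v)
    for pos in profile.window.positions():
        slot = by_pos.get(pos)
        if slot is None:
            out.append(reference.base_at(pos))
            continue
        if slot["del"]:
            pass
        elif slot["sub"] is not None:
            out.append(slot["sub"])
        else:
            out.append(reference.base_at(pos))
        for ins in sorted(slot["ins"], key=lambda v: v.insertion_index):
            out.append(ins.derived_base)
    return "".join(out)
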