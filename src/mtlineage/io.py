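"""Readers and writers for sequences, variant tables and population maps.

Formats are deliberately plain text: FASTA for sequences, TSV for the
EMPOP-style rCRS-relative haplotype tables and for sample->population maps.
"""

from __future__ import annotations

import io as _io
from importlib import resources
from typing import Iterable, Mapping

from Bio import SeqIO

from .coords import MT_LENGTH, CoordinateWindow, ReferenceSequence
from .variants import (
    HaplotypeProfile,
    VariantFormatError,
    format_variants,
    parse_variant,
)

UNSPECIFIED = "unspecified"


class InputError(ValueError):
    """Malformed or inconsistent input data."""


def _as_handle(stream):
    if isinstance(stream, str):
        return _io.StringIO(stream)
    return stream


def parse_fasta(
    stream,
    population_map: Mapping[str, str] | None = None,
    default_population: str | None = None,
) -> list[tuple[str, str, str]]:
    """Read FASTA records as (sample_id, sequence, population) tuples.

    Sequences are upper-cased and U is normalised to T. Every record id must
    resolve through *population_map* or *default_population* (use
    ``UNSPECIFIED`` to accept unlabelled samples explicitly).
    """
    population_map = population_map or {}
    out: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_as_handle(stream), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate sample id {rec.id!r} in FASTA")
        seen.add(rec.id)
        pop = population_map.get(rec.id, default_population)
        if pop is None:
            raise InputError(
                f"sample {rec.id!r} has no population and no default given"
            )
        seq = str(rec.seq).upper().replace("U", "T")
        out.append((rec.id, seq, pop))
    if not out:
        raise InputError("empty FASTA input")
    return out


def write_fasta(records: Iterable[tuple[str, str]], handle) -> None:
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")
    finally:
        if close:
            handle.close()


def read_population_map(stream) -> dict[str, str]:
    """Two-column TSV: sample_id <tab> population."""
    out: dict[str, str] = {}
    for ln, line in enumerate(_as_handle(stream), 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"population map line {ln}: expected 2 columns")
        out[parts[0]] = parts[1]
    return out


def write_population_map(pairs: Iterable[tuple[str, str]], handle) -> None:
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        for sid, pop in pairs:
            handle.write(f"{sid}\t{pop}\n")
    finally:
        if close:
            handle.close()


_TABLE_HEADER = ["sample_id", "population", "window_start", "window_end", "variants"]


def read_variant_table(stream) -> list[HaplotypeProfile]:
    """Read an rCRS-relative haplotype table (one row per sample)."""
    profiles: list[HaplotypeProfile] = []
    seen: set[str] = set()
    lines = list(_as_handle(stream))
    if not lines:
        raise InputError("empty variant table")
    start = 1 if lines[0].rstrip("\n").split("\t")[:2] == _TABLE_HEADER[:2] else 0
    for ln, line in enumerate(lines[start:], start + 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise InputError(f"variant table row {ln}: expected >=4 columns")
        sid, pop, ws, we = parts[:4]
        tokens = parts[4].split() if len(parts) > 4 and parts[4] else []
        if sid in seen:
            raise InputError(f"variant table row {ln}: duplicate sample {sid!r}")
        seen.add(sid)
        try:
            wstart, wend = int(ws), int(we)
        except ValueError as exc:
            raise InputError(f"variant table row {ln}: bad window") from exc
        window = CoordinateWindow(wstart, wend, circular=wstart > wend)
        calls = []
        for tok in tokens:
            try:
                calls.append(parse_variant(tok))
            except VariantFormatError as exc:
                raise InputError(
                    f"variant table row {ln}: bad token {tok!r}"
                ) from exc
        profiles.append(HaplotypeProfile(sid, pop, window, frozenset(calls)))
    return profiles


def write_variant_table(profiles: Iterable[HaplotypeProfile], handle) -> None:
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("\t".join(_TABLE_HEADER) + "\n")
        for p in profiles:
            handle.write(
                "\t".join(
                    [
                        p.sample_id,
                        p.population,
                        str(p.window.start),
                        str(p.window.end),
                        format_variants(p.variants),
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def load_reference() -> ReferenceSequence:
    """Load the packaged synthetic rCRS-like reference (16,569 bp).

    This is a synthetic stand-in sequence with rCRS geometry (length,
    circularity, the classic poly-C tracts around np 303-315 and np
    16184-16193), not the true NC_012920.1 sequence. All coordinates in the
    package are expressed on this reference.
    """
    ref = resources.files("mtlineage.data").joinpath(
        "synthetic_rcrs_like.fasta"
    )
    with ref.open() as fh:
        recs = list(SeqIO.parse(fh, "fasta"))
    seq = str(recs[0].seq).upper()
    if len(seq) != MT_LENGTH:
        raise InputError("packaged reference has wrong length")
    return ReferenceSequence(recs[0].id, seq)
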