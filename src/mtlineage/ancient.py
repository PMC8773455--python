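"""Spatiotemporal tracing of maternal lineages through ancient mitogenomes.

For each lineage seen in a modern population, dated and georeferenced ancient
mitogenomes decide whether the lineage was already present in a longitude
band of interest before a calendar cutoff (default 1000 BCE), arrived after
it, or is absent from the band. Arrivals are additionally flagged as
trade-route consistent when the earliest record in the band is preceded by an
older record a configurable 20-40 degrees of longitude further west.

Dates are signed calendar years CE (-1000 = 1000 BCE); before-present inputs
are converted with the 1950 datum at parse time.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .haplotree import MotifTree

BP_DATUM = 1950


class AncientDataError(ValueError):
    pass


@dataclass(frozen=True)
class AncientRecord:
    record_id: str
    haplogroup: str
    date_ce: float
    longitude: float
    latitude: float
    site: str = ""

    def __post_init__(self) -> None:
        if not -50000 < self.date_ce < 2100:
            raise AncientDataError(
                f"{self.record_id}: implausible date {self.date_ce}"
            )
        if not -180 <= self.longitude <= 180:
            raise AncientDataError(
                f"{self.record_id}: longitude {self.longitude} out of range"
            )


@dataclass(frozen=True)
class RegionBand:
    name: str
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if self.lon_min >= self.lon_max:
            raise AncientDataError("band lon_min must be < lon_max")

    def contains(self, longitude: float) -> bool:
        return self.lon_min <= longitude <= self.lon_max


#: "Mongolia or nearby regions" default longitude band
MONGOLIA_BAND = RegionBand("mongolia_and_nearby", 85.0, 125.0)

PRE_CUTOFF = "pre_cutoff_presence"
POST_CUTOFF = "post_cutoff_arrival"
ABSENT = "absent_in_band"


@dataclass(frozen=True)
class TraceResult:
    lineage: str
    status: str
    earliest_in_band: AncientRecord | None
    earliest_western_precursor: AncientRecord | None
    lon_offset: float | None
    route_consistent: bool


def _is_digit_letter_boundary(prefix: str, name: str) -> bool:
    """Proper nested-clade extension: the token type must switch at the cut.

    "H5a1" extends to "H5a1a" (digit -> letter) but "H5" does not match
    "H51" (the trailing number continues).
    """
    nxt = name[len(prefix)]
    last = prefix[-1]
    if last.isdigit():
        return not nxt.isdigit()
    return nxt.isdigit()


def lineage_match(
    record_haplogroup: str, lineage: str, tree: MotifTree | None = None
) -> bool:
    """True iff the record's haplogroup is the lineage or nested within it."""
    if tree is not None:
        for name in (record_haplogroup, lineage):
            if name not in tree:
                raise AncientDataError(f"haplogroup {name!r} not in motif tree")
        return tree.is_descendant(record_haplogroup, lineage)
    if record_haplogroup == lineage:
        return True
    if record_haplogroup.startswith(lineage):
        return _is_digit_letter_boundary(lineage, record_haplogroup)
    return False


def trace_lineage(
    lineage: str,
    records: Sequence[AncientRecord],
    band: RegionBand = MONGOLIA_BAND,
    cutoff_ce: float = -1000.0,
    offset_range: tuple[float, float] = (20.0, 40.0),
    tree: MotifTree | None = None,
) -> TraceResult:
    """Classify one lineage's arrival history in the band of interest."""
    if not records:
        raise AncientDataError("empty ancient record set")
    matching = [r for r in records if lineage_match(r.haplogroup, lineage, tree)]
    in_band = [r for r in matching if band.contains(r.longitude)]
    if not in_band:
        return TraceResult(lineage, ABSENT, None, None, None, False)
    earliest = min(in_band, key=lambda r: (r.date_ce, r.record_id))
    status = PRE_CUTOFF if earliest.date_ce <= cutoff_ce else POST_CUTOFF
    west = [r for r in matching if r.longitude < earliest.longitude]
    precursor = (
        min(west, key=lambda r: (r.date_ce, r.longitude, r.record_id))
        if west
        else None
    )
    offset = earliest.longitude - precursor.longitude if precursor else None
    consistent = bool(
        status == POST_CUTOFF
        and precursor is not None
        and offset_range[0] <= offset <= offset_range[1]
        and precursor.date_ce < earliest.date_ce
    )
    return TraceResult(lineage, status, earliest, precursor, offset, consistent)


def trace_report(
    lineages: Iterable[str],
    records: Sequence[AncientRecord],
    band: RegionBand = MONGOLIA_BAND,
    cutoff_ce: float = -1000.0,
    offset_range: tuple[float, float] = (20.0, 40.0),
    tree: MotifTree | None = None,
) -> tuple[list[TraceResult], dict[str, int]]:
    """Trace every lineage; return results plus status/route summary counts."""
    results = [
        trace_lineage(ln, records, band, cutoff_ce, offset_range, tree)
        for ln in lineages
    ]
    summary = {PRE_CUTOFF: 0, POST_CUTOFF: 0, ABSENT: 0, "route_consistent": 0}
    for r in results:
        summary[r.status] += 1
        if r.route_consistent:
            summary["route_consistent"] += 1
    return results, summary


def results_table(results: Sequence[TraceResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "lineage": r.lineage,
                "status": r.status,
                "earliest_in_band_id": r.earliest_in_band.record_id if r.earliest_in_band else "",
                "earliest_in_band_date_ce": r.earliest_in_band.date_ce if r.earliest_in_band else "",
                "precursor_id": r.earliest_western_precursor.record_id if r.earliest_western_precursor else "",
                "precursor_date_ce": r.earliest_western_precursor.date_ce if r.earliest_western_precursor else "",
                "lon_offset": "" if r.lon_offset is None else r.lon_offset,
                "route_consistent": r.route_consistent,
            }
        )
    return pd.DataFrame(rows)


def load_ancient_table(stream) -> list[AncientRecord]:
    """TSV with record_id, haplogroup, date_ce or date_bp, longitude, latitude, site."""
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", comment="#")
    need = {"record_id", "haplogroup", "longitude", "latitude"}
    if not need <= set(df.columns):
        raise AncientDataError(f"ancient table missing columns {need - set(df.columns)}")
    if "date_ce" not in df.columns and "date_bp" not in df.columns:
        raise AncientDataError("ancient table needs date_ce or date_bp")
    records = []
    for _, row in df.iterrows():
        if "date_ce" in df.columns and pd.notna(row.get("date_ce")):
            date = float(row["date_ce"])
        elif "date_bp" in df.columns and pd.notna(row.get("date_bp")):
            date = BP_DATUM - float(row["date_bp"])
        else:
            raise AncientDataError(f"{row['record_id']}: no usable date")
        records.append(
            AncientRecord(
                record_id=str(row["record_id"]),
                haplogroup=str(row["haplogroup"]),
                date_ce=date,
                longitude=float(row["longitude"]),
                latitude=float(row["latitude"]),
                site="" if pd.isna(row.get("site")) else str(row.get("site")),
            )
        )
    return records


def write_ancient_table(records: Sequence[AncientRecord], handle) -> None:
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("record_id\thaplogroup\tdate_ce\tlongitude\tlatitude\tsite\n")
        for r in records:
            handle.write(
                f"{r.record_id}\t{r.haplogroup}\t{r.date_ce:g}\t"
                f"{r.longitude:g}\t{r.latitude:g}\t{r.site}\n"
            )
    finally:
        if close:
            handle.close()
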