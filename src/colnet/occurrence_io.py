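"""Reading, validating and filtering species-occurrence tables.

Occurrence tables are delimited text with a header row using Darwin Core
term names (``recordedBy``, ``scientificName``, ``taxonRank``, ...), or any
header at all when a ``column_map`` translates Darwin Core terms to the
file's own column names.  Only ``recordedBy`` and ``scientificName`` are
mandatory; everything else is optional and parsed leniently — dates and
coordinates never cause a record to be dropped, because the network models
built downstream are temporally and geographically invariant.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from colnet.errors import ConfigurationError

#: Darwin Core terms the reader understands, in canonical column order.
DWC_TERMS = (
    "recordedBy",
    "scientificName",
    "taxonRank",
    "family",
    "eventDate",
    "countryCode",
    "stateProvince",
    "decimalLatitude",
    "decimalLongitude",
    "issue",
)

MANDATORY_TERMS = ("recordedBy", "scientificName")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One specimen record, the unit both network models are built from."""

    record_id: str
    recorded_by_raw: str
    taxon_name: str
    taxon_rank: str = "species"
    collector_ids: tuple[str, ...] = ()
    family: Optional[str] = None
    event_date: Optional[str] = None
    country_code: Optional[str] = None
    state_province: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    issues: Optional[str] = None

    def with_collectors(self, ids: Sequence[str]) -> "OccurrenceRecord":
        """Return a copy with resolved collector ids (deduplication is the
        resolver's job; this just stores them)."""
        return replace(self, collector_ids=tuple(ids))


@dataclass
class RecordFilterConfig:
    """Which records to keep before building a network.

    The default keeps everything; per-model presets are provided because the
    SCN needs both a collector and a taxon, while the CWN only needs the
    collector side.
    """

    require_collectors: bool = False
    require_taxon: bool = False
    allowed_ranks: Optional[frozenset[str]] = None
    drop_issue_patterns: tuple[str, ...] = ()

    def __post_init__(self):
        if self.allowed_ranks is not None:
            self.allowed_ranks = frozenset(r.lower() for r in self.allowed_ranks)
            if not self.allowed_ranks:
                raise ConfigurationError("allowed_ranks must be nonempty when rank filtering is enabled")

    @classmethod
    def for_scn(cls, ranks: Iterable[str] = ("species",)) -> "RecordFilterConfig":
        return cls(require_collectors=True, require_taxon=True, allowed_ranks=frozenset(ranks))

    @classmethod
    def for_cwn(cls) -> "RecordFilterConfig":
        return cls(require_collectors=True)


@dataclass
class ReadReport:
    rows_read: int = 0
    rows_empty_recorded_by: int = 0
    rows_empty_scientific_name: int = 0


def _parse_float(value: str) -> Optional[float]:
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def read_occurrences(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
) -> tuple[list[OccurrenceRecord], ReadReport]:
    """Read an occurrence table into canonical records.

    Parameters
    ----------
    path:
        Delimited UTF-8 text file with a header row.
    column_map:
        Mapping from Darwin Core term to the file's column name.  Defaults to
        the identity map (header already uses Darwin Core terms).
    delimiter:
        Field separator; sniffed from the header line (comma vs tab) when
        omitted.

    Returns
    -------
    (records, report):
        One record per data row, in file order, with raw fields verbatim.
        Rows with empty mandatory fields are retained (filtering is a
        separate, explicit step) but counted in the report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(column_map) if column_map else {t: t for t in DWC_TERMS}
    for term in MANDATORY_TERMS:
        if term not in colmap:
            raise ConfigurationError(f"column_map must cover mandatory term {term!r}")

    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","

    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8")
    for term in MANDATORY_TERMS:
        if colmap[term] not in df.columns:
            raise ConfigurationError(f"mandatory column {colmap[term]!r} (term {term!r}) absent from header")

    def col(row, term):
        name = colmap.get(term)
        if name is None or name not in df.columns:
            return ""
        return row[name].strip()

    id_col = colmap.get("record_id")
    records: list[OccurrenceRecord] = []
    report = ReadReport()
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        recorded_by = col(row, "recordedBy")
        taxon = col(row, "scientificName")
        report.rows_read += 1
        if not recorded_by:
            report.rows_empty_recorded_by += 1
        if not taxon:
            report.rows_empty_scientific_name += 1
        rid = row[id_col].strip() if id_col and id_col in df.columns else f"r{i}"
        records.append(
            OccurrenceRecord(
                record_id=rid,
                recorded_by_raw=recorded_by,
                taxon_name=taxon,
                taxon_rank=col(row, "taxonRank").lower() or "species",
                family=col(row, "family") or None,
                event_date=col(row, "eventDate") or None,
                country_code=col(row, "countryCode") or None,
                state_province=col(row, "stateProvince") or None,
                latitude=_parse_float(col(row, "decimalLatitude")),
                longitude=_parse_float(col(row, "decimalLongitude")),
                issues=col(row, "issue") or None,
            )
        )
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("record ids are not unique within the dataset")
    return records, report


def filter_records(
    records: Sequence[OccurrenceRecord], cfg: RecordFilterConfig
) -> tuple[list[OccurrenceRecord], list[tuple[str, str]]]:
    """Partition records into (kept, dropped) under a filter configuration.

    Every dropped entry carries exactly one primary reason — the first
    failing check in the order: collectors, taxon, rank, issue patterns.
    With all filters disabled the kept list equals the input.
    """
    kept: list[OccurrenceRecord] = []
    dropped: list[tuple[str, str]] = []
    for rec in records:
        reason = None
        if cfg.require_collectors and not (rec.recorded_by_raw or rec.collector_ids):
            reason = "no-collectors"
        elif cfg.require_taxon and not rec.taxon_name:
            reason = "no-taxon"
        elif cfg.allowed_ranks is not None and rec.taxon_rank.lower() not in cfg.allowed_ranks:
            reason = f"rank-not-allowed:{rec.taxon_rank}"
        elif cfg.drop_issue_patterns and rec.issues:
            for pat in cfg.drop_issue_patterns:
                if pat in rec.issues:
                    reason = f"issue:{pat}"
                    break
        if reason is None:
            kept.append(rec)
        else:
            dropped.append((rec.record_id, reason))
    return kept, dropped


def write_occurrences(records: Iterable[OccurrenceRecord], path, delimiter: str = ",") -> None:
    """Write records back out as a Darwin Core-style table.

    The output reads back through :func:`read_occurrences` with mandatory
    fields preserved verbatim (round-trip property).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(["record_id", *DWC_TERMS])
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.recorded_by_raw,
                    r.taxon_name,
                    r.taxon_rank,
                    r.family or "",
                    r.event_date or "",
                    r.country_code or "",
                    r.state_province or "",
                    "" if r.latitude is None else repr(r.latitude),
                    "" if r.longitude is None else repr(r.longitude),
                    r.issues or "",
                ]
            )
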