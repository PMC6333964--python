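"""Reading and writing GEO series metadata.

GEO distributes series metadata in SOFT, a line-oriented plain-text format
(``^SERIES`` / ``!Series_*`` records), and GEOmetadb republishes the same
fields as relational tables.  This module reads both into a single
:class:`SeriesMetadata` record, flags super-series (bundles of sub-series
that must not enter time-point detection), and writes restructured records
— time-point counts, time values and Disease Ontology annotations — as
JSON-lines, CSV or a SQLite table.
"""

from __future__ import annotations

import csv
import io
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "SeriesMetadata",
    "SoftParseError",
    "parse_soft_series",
    "parse_tabular",
    "is_superseries",
    "write_restructured",
    "read_restructured",
    "RECORD_COLUMNS",
]

#: GEOmetadb-style auxiliary columns carried through to the output record.
AUX_FIELDS = (
    "platform_id",
    "platform_organism",
    "platform_taxid",
    "sample_organism",
    "sample_taxid",
    "contributor",
    "contact",
    "last_update_date",
    "submission_date",
)

#: Output schema of the restructured record, in column order.
RECORD_COLUMNS = (
    "gse",
    "title",
    "type",
    "organism",
    "pubmed_id",
    "submission_date",
    "last_update_date",
    "platform_id",
    "platform_organism",
    "platform_taxid",
    "sample_organism",
    "sample_taxid",
    "contributor",
    "contact",
    "n_timepoints",
    "time_values",
    "timepoint_scenario",
    "is_superseries",
    "DOID_termIDs",
    "DOID_termName",
    "DOID_isLeaf",
    "DOID_distancefromRoot",
    "DOID_isObsolete",
)

_INT_COLUMNS = {"n_timepoints", "is_superseries"}


class SoftParseError(ValueError):
    """Raised when a SOFT stream has no recognisable ``^SERIES`` block."""

    def __init__(self, message: str, byte_offset: int):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset


@dataclass
class SeriesMetadata:
    """One GEO series' metadata, structured and free-text fields together.

    Every text field defaults to the empty string, never ``None``, so
    downstream regex passes need no absence branches.
    """

    accession: str
    title: str = ""
    summary: str = ""
    overall_design: str = ""
    series_type: str = ""
    organism: str = ""
    pubmed_id: str = ""
    abstract: str = ""
    sample_titles: list[str] = field(default_factory=list)
    aux: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("SeriesMetadata.accession must be non-empty")


# --- SOFT parsing -----------------------------------------------------------

# Attribute lines mapped onto SeriesMetadata fields; everything else that
# starts with !Series_ goes into aux.  Only ^SERIES, ^SAMPLE, !Series_* and
# !Sample_title lines are interpreted; all other lines are ignored.
_SERIES_ATTR_MAP = {
    "title": "title",
    "summary": "summary",
    "overall_design": "overall_design",
    "type": "series_type",
    "organism": "organism",
    "sample_organism": "organism",
    "pubmed_id": "pubmed_id",
}


def parse_soft_series(stream: IO[str] | str) -> SeriesMetadata:
    """Parse one series from a SOFT-format text stream.

    Repeated attribute lines (e.g. multi-paragraph ``!Series_summary``) are
    concatenated with a single space in file order; sample titles are
    returned in file order.  Tolerant of CRLF line endings and trailing
    whitespace.

    Raises
    ------
    SoftParseError
        If the stream contains no ``^SERIES`` line; the error names the
        byte offset at which scanning gave up.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    accession = ""
    fields: dict[str, list[str]] = {}
    aux: dict[str, str] = {}
    sample_titles: list[str] = []
    in_sample = False
    seen_series = False
    offset = 0

    for raw in stream:
        line_len = len(raw.encode("utf-8", errors="replace"))
        line = raw.rstrip()
        if line.startswith("^SERIES"):
            seen_series = True
            in_sample = False
            _, _, value = line.partition("=")
            accession = value.strip()
        elif line.startswith("^SAMPLE"):
            in_sample = True
        elif line.startswith("!Series_"):
            key, _, value = line.partition("=")
            key = key[len("!Series_"):].strip().lower()
            value = value.strip()
            target = _SERIES_ATTR_MAP.get(key)
            if target is not None:
                fields.setdefault(target, []).append(value)
            else:
                aux[key] = f"{aux[key]} {value}" if key in aux else value
        elif line.startswith("!Sample_title") and in_sample:
            _, _, value = line.partition("=")
            sample_titles.append(value.strip())
        offset += line_len

    if not seen_series:
        raise SoftParseError("no ^SERIES block found in SOFT stream", offset)

    joined = {k: " ".join(v) for k, v in fields.items()}
    return SeriesMetadata(
        accession=accession or "GSE_UNKNOWN",
        title=joined.get("title", ""),
        summary=joined.get("summary", ""),
        overall_design=joined.get("overall_design", ""),
        series_type=joined.get("series_type", ""),
        organism=joined.get("organism", ""),
        pubmed_id=joined.get("pubmed_id", ""),
        sample_titles=sample_titles,
        aux=aux,
    )


# --- Tabular ingestion ------------------------------------------------------

# GEOmetadb column name (lower-case) -> SeriesMetadata attribute.
_TABULAR_MAP = {
    "gse": "accession",
    "accession": "accession",
    "title": "title",
    "summary": "summary",
    "overall_design": "overall_design",
    "type": "series_type",
    "organism": "organism",
    "pubmed_id": "pubmed_id",
    "abstract": "abstract",
}


def parse_tabular(rows: Iterable[Mapping[str, object]]) -> list[SeriesMetadata]:
    """Build SeriesMetadata records from tabular rows (GEOmetadb column set).

    Column names are matched case-insensitively.  A ``sample_titles``
    column, if present, is split on ``;``.  Known auxiliary columns and any
    unrecognised columns are preserved in ``aux``.  Duplicate accessions
    raise a ``ValueError`` listing the duplicates.

    Accepts any iterable of mappings; pass ``df.to_dict("records")`` for a
    pandas DataFrame.
    """
    out: list[SeriesMetadata] = []
    seen: dict[str, int] = {}
    for row in rows:
        kwargs: dict[str, object] = {}
        aux: dict[str, str] = {}
        sample_titles: list[str] = []
        for key, value in row.items():
            lkey = str(key).lower()
            text = "" if value is None else str(value)
            if lkey in _TABULAR_MAP:
                kwargs[_TABULAR_MAP[lkey]] = text
            elif lkey == "sample_titles":
                sample_titles = [t for t in text.split(";") if t]
            else:
                aux[lkey] = text
        accession = str(kwargs.get("accession", ""))
        if not accession:
            raise ValueError("tabular row without an accession (gse) column")
        seen[accession] = seen.get(accession, 0) + 1
        meta = SeriesMetadata(
            accession=accession,
            title=str(kwargs.get("title", "")),
            summary=str(kwargs.get("summary", "")),
            overall_design=str(kwargs.get("overall_design", "")),
            series_type=str(kwargs.get("series_type", "")),
            organism=str(kwargs.get("organism", "")),
            pubmed_id=str(kwargs.get("pubmed_id", "")),
            abstract=str(kwargs.get("abstract", "")),
            sample_titles=sample_titles,
            aux=aux,
        )
        out.append(meta)
    dupes = sorted(acc for acc, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate accessions in tabular input: {dupes}")
    return out


def is_superseries(meta: SeriesMetadata) -> bool:
    """True iff the series is a GEO super-series.

    Super-series bundle sub-series analysed individually, so they are
    excluded from time-point detection (but still disease-tagged).  A
    series is flagged when its type field contains "superseries" or its
    summary carries the GEO "SuperSeries" boilerplate, case-insensitively.
    Pure function of ``series_type`` and ``summary``.
    """
    stype = meta.series_type.replace(" ", "").replace("-", "").lower()
    if "superseries" in stype:
        return True
    return "superseries" in meta.summary.replace(" ", "").replace("-", "").lower()


# --- Restructured record output --------------------------------------------


def _build_record(meta, time_result, tags) -> dict[str, object]:
    from .timepoints import format_time_value  # local import: avoid cycle

    values = sorted(
        time_result.final_values,
        key=lambda v: (v.canonical_hours is None, v.canonical_hours or 0.0, v.magnitude),
    )
    record: dict[str, object] = {
        "gse": meta.accession,
        "title": meta.title,
        "type": meta.series_type,
        "organism": meta.organism,
        "pubmed_id": meta.pubmed_id,
    }
    for name in AUX_FIELDS:
        record.setdefault(name, meta.aux.get(name, ""))
    record["submission_date"] = meta.aux.get("submission_date", "")
    record["last_update_date"] = meta.aux.get("last_update_date", "")
    record["n_timepoints"] = int(time_result.final_count)
    record["time_values"] = ";".join(format_time_value(v) for v in values)
    record["timepoint_scenario"] = time_result.winning_scenario or ""
    record["is_superseries"] = int(time_result.excluded)
    record["DOID_termIDs"] = "|".join(t.doid for t in tags)
    record["DOID_termName"] = "|".join(t.term_name for t in tags)
    record["DOID_isLeaf"] = "|".join(str(int(t.is_leaf)) for t in tags)
    record["DOID_distancefromRoot"] = "|".join(str(t.distance_from_root) for t in tags)
    record["DOID_isObsolete"] = "|".join(str(int(t.is_obsolete)) for t in tags)
    return {col: record[col] for col in RECORD_COLUMNS}


def write_restructured(results: Sequence[tuple], sink: str | Path, format: str = "jsonl") -> Path:
    """Write restructured records, one per series.

    Each element of ``results`` is ``(SeriesMetadata, SeriesTimeResult,
    list_of_DiseaseTag)``.  Tag lists serialise as parallel pipe-joined
    strings, time values as a canonical-order semicolon-joined string.
    Reading the file back with :func:`read_restructured` reproduces the
    records bit-exactly.
    """
    sink = Path(sink)
    records = [_build_record(m, r, t) for (m, r, t) in results]
    if format == "jsonl":
        with open(sink, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(RECORD_COLUMNS))
            writer.writeheader()
            writer.writerows(records)
    elif format == "sqlite":
        if sink.exists():
            sink.unlink()
        cols = ", ".join(
            f'"{c}" INTEGER' if c in _INT_COLUMNS else f'"{c}" TEXT'
            for c in RECORD_COLUMNS
        )
        with sqlite3.connect(sink) as conn:
            conn.execute(f"CREATE TABLE regeo ({cols})")
            placeholders = ", ".join("?" for _ in RECORD_COLUMNS)
            conn.executemany(
                f"INSERT INTO regeo VALUES ({placeholders})",
                [tuple(rec[c] for c in RECORD_COLUMNS) for rec in records],
            )
        conn.close()
    else:
        raise ValueError(f"unknown output format: {format!r}")
    return sink


def read_restructured(source: str | Path, format: str = "jsonl") -> list[dict[str, object]]:
    """Read records written by :func:`write_restructured` (round-trip inverse)."""
    source = Path(source)
    if format == "jsonl":
        with open(source, encoding="utf-8") as fh:
            return [json.loads(line) for line in fh if line.strip()]
    if format == "csv":
        with open(source, encoding="utf-8", newline="") as fh:
            records = []
            for row in csv.DictReader(fh):
                for col in _INT_COLUMNS:
                    row[col] = int(row[col])
                records.append(dict(row))
            return records
    if format == "sqlite":
        with sqlite3.connect(source) as conn:
            cur = conn.execute(
                "SELECT {} FROM regeo".format(", ".join(f'"{c}"' for c in RECORD_COLUMNS))
            )
            rows = cur.fetchall()
        conn.close()
        return [dict(zip(RECORD_COLUMNS, row)) for row in rows]
    raise ValueError(f"unknown output format: {format!r}")
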