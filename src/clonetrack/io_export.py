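"""Lossless serialization of report tables to CSV, XML, and JSON.

The contract is exact round-trip identity: ``import_table(export_table(t,
fmt))`` reproduces ``t`` — same columns, same row order, same cell values
— for every supported format, and exporting a fixed table is
byte-deterministic (stable field order, no timestamps).

Formats:

* **CSV** — RFC 4180 with a header row. CSV cannot distinguish a missing
  value from an empty string, so missing serializes as the empty field
  (tables normalize ``""`` to missing at construction).
* **XML** — the minimal lossless mapping of a rectangular table:
  ``<records><record><field name="col">value</field>...</record></records>``;
  a missing value is an absent element.
* **JSON** — an array of flat objects keyed by column name; missing is
  ``null``.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from typing import Literal

from lxml import etree

from .errors import ImportError_, SchemaError
from .reports import ReportTable

Format = Literal["csv", "xml", "json"]

FORMATS: tuple[Format, ...] = ("csv", "xml", "json")


@dataclass(frozen=True)
class ExportDocument:
    format: Format
    payload: str
    columns: tuple[str, ...]


def export_table(table: ReportTable, format: Format) -> ExportDocument:
    """Serialize ``table``; duplicate or empty column names are refused at
    table construction, so any ReportTable exports cleanly."""
    if format == "csv":
        payload = table.to_csv()
    elif format == "json":
        payload = json.dumps(
            [dict(zip(table.columns, row)) for row in table.rows],
            ensure_ascii=False,
            indent=2,
        )
    elif format == "xml":
        root = etree.Element("records")
        for row in table.rows:
            rec = etree.SubElement(root, "record")
            for col, value in zip(table.columns, row):
                if value is None:
                    continue
                elem = etree.SubElement(rec, "field", name=col)
                elem.text = value
        payload = etree.tostring(
            root, encoding="unicode", pretty_print=True
        )
    else:
        raise SchemaError(f"unknown export format {format!r}")
    return ExportDocument(format, payload, table.columns)


def import_table(doc: ExportDocument) -> ReportTable:
    """Reconstruct the table from an export document; malformed payloads
    raise :class:`ImportError_` carrying the offending locus."""
    if doc.format == "csv":
        return _import_csv(doc)
    if doc.format == "json":
        return _import_json(doc)
    if doc.format == "xml":
        return _import_xml(doc)
    raise SchemaError(f"unknown export format {doc.format!r}")


def _import_csv(doc: ExportDocument) -> ReportTable:
    reader = csv.reader(io.StringIO(doc.payload, newline=""))
    try:
        header = next(reader)
    except StopIteration:
        raise ImportError_("CSV payload is empty (line 1)") from None
    if tuple(header) != doc.columns:
        raise ImportError_(
            f"CSV header {header!r} does not match schema {doc.columns!r} (line 1)"
        )
    rows = []
    for lineno, row in enumerate(reader, start=2):
        if len(row) != len(doc.columns):
            raise ImportError_(
                f"CSV row of width {len(row)} under {len(doc.columns)} "
                f"columns (record {lineno - 1})"
            )
        rows.append(tuple(None if cell == "" else cell for cell in row))
    return ReportTable(doc.columns, tuple(rows))


def _import_json(doc: ExportDocument) -> ReportTable:
    try:
        data = json.loads(doc.payload)
    except json.JSONDecodeError as exc:
        raise ImportError_(f"JSON parse error at line {exc.lineno}: {exc.msg}") from None
    if not isinstance(data, list):
        raise ImportError_("JSON payload must be an array of objects")
    rows = []
    for i, obj in enumerate(data):
        if not isinstance(obj, dict) or set(obj) != set(doc.columns):
            raise ImportError_(f"JSON record {i} does not match the schema")
        rows.append(tuple(obj[c] for c in doc.columns))
    return ReportTable(doc.columns, tuple(rows))


def _import_xml(doc: ExportDocument) -> ReportTable:
    try:
        root = etree.fromstring(doc.payload.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ImportError_(f"XML parse error: {exc}") from None
    if root.tag != "records":
        raise ImportError_(f"unexpected root element <{root.tag}>")
    rows = []
    for i, rec in enumerate(root):
        if rec.tag != "record":
            raise ImportError_(f"unexpected element <{rec.tag}> at record {i}")
        values = {}
        for elem in rec:
            name = elem.get("name")
            if elem.tag != "field" or name is None:
                raise ImportError_(f"malformed field element in record {i}")
            values[name] = elem.text if elem.text is not None else ""
        unknown = set(values) - set(doc.columns)
        if unknown:
            raise ImportError_(f"record {i} carries unknown fields {sorted(unknown)}")
        rows.append(tuple(values.get(c) for c in doc.columns))
    return ReportTable(doc.columns, tuple(rows))


def write_document(doc: ExportDocument, path) -> None:
    """Write the payload as UTF-8; CSV keeps its RFC 4180 CRLF line ends."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(doc.payload)
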