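"""Reading and writing the tool's tab-delimited expression contract.

The input contract is deliberately loose: a tab-delimited table whose
first column is an Ensembl gene ID (when known) and whose second
column is a gene symbol or GenBank accession. Any further columns are
carried through verbatim, so existing Cufflinks (or similar) output can
be annotated without losing information. Columns whose header names a
transcript/tracking ID or an FPKM are additionally parsed into typed
fields. A dedicated adapter maps the Cufflinks ``*.fpkm_tracking``
dialect onto the same record type.

FPKM values are kept both as parsed floats and as the exact input
strings; output echoes the strings, so a read/annotate/write round
trip never re-rounds anything.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .annotation_ingest import _open_text
from .association_engine import (
    AssociationQuery,
    AssociationResult,
    Method,
    associate,
)
from .errors import ParseError, SchemaError
from .xref_store import XrefStore

logger = logging.getLogger(__name__)

CUFFLINKS_MISSING = "-"
PROBE_JOIN = "///"

# Column-1 values that mark a data (not header) row when no header flag
# is given: Ensembl genes, Cufflinks novel genes, or the missing token.
_ID_PATTERN = re.compile(r"^(ENSG\d+|CUFF\.\d+.*|-)$")
_TRANSCRIPT_COL_RE = re.compile(r"(transcript|tracking)[ _]?id", re.IGNORECASE)
_FPKM_COL_RE = re.compile(r"fpkm", re.IGNORECASE)
_GENE_FPKM_COL_RE = re.compile(r"gene.*fpkm", re.IGNORECASE)


@dataclass
class ExpressionRecord:
    """One input row: gene ID, label, optional typed fields, extras."""

    gene_id: str
    label: str
    transcript_id: str | None = None
    fpkm: float | None = None
    fpkm_raw: str | None = None
    extra: tuple[tuple[str, str], ...] = ()

    def extra_value(self, column: str) -> str | None:
        for name, value in self.extra:
            if name == column:
                return value
        return None


@dataclass
class AnnotatedRecord:
    """An expression record plus its probe-set association."""

    record: ExpressionRecord
    association: AssociationResult
    microarray_expression: float | None = None
    cytoband: str | None = None


def _clean(cell: str) -> str:
    cell = cell.strip()
    return "" if cell == CUFFLINKS_MISSING else cell


def read_expression_table(source, has_header: bool | None = None) -> list[ExpressionRecord]:
    """Read the generic tab-delimited contract.

    Column 1 is the gene ID, column 2 the label; all further columns are
    preserved as extras in input order. A header row is auto-detected
    (first row whose column 1 is not ID-shaped) unless ``has_header``
    is forced. Headers matching transcript/tracking-ID or FPKM names
    also populate the typed fields; a non-numeric value under an FPKM
    header is a row-level warning, not an error.
    """
    handle, close = _open_text(source)
    try:
        records: list[ExpressionRecord] = []
        header: list[str] | None = None
        first = True
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"expected >=2 tab-separated columns, found {len(fields)}", lineno
                )
            if first:
                first = False
                is_header = (
                    has_header
                    if has_header is not None
                    else not _ID_PATTERN.match(fields[0].strip())
                )
                if is_header:
                    header = [h.strip() for h in fields]
                    continue
                header = None
            if header is not None and len(fields) < len(header):
                fields = fields + [""] * (len(header) - len(fields))
            gene_id, label = _clean(fields[0]), _clean(fields[1])
            extra_cols = fields[2:]
            if header is not None:
                extra_names = header[2:]
            else:
                extra_names = [f"col{i}" for i in range(3, 3 + len(extra_cols))]
            transcript_id: str | None = None
            fpkm: float | None = None
            fpkm_raw: str | None = None
            extras: list[tuple[str, str]] = []
            for name, value in zip(extra_names, extra_cols):
                if _TRANSCRIPT_COL_RE.search(name) and transcript_id is None:
                    transcript_id = _clean(value) or None
                elif (
                    fpkm_raw is None
                    and not _GENE_FPKM_COL_RE.search(name)
                    and _FPKM_COL_RE.search(name)
                ):
                    raw = _clean(value)
                    if raw:
                        try:
                            parsed = float(raw)
                        except ValueError:
                            logger.warning(
                                "line %d: non-numeric FPKM %r, leaving absent",
                                lineno,
                                value,
                            )
                        else:
                            if parsed < 0:
                                logger.warning(
                                    "line %d: negative FPKM %r, leaving absent",
                                    lineno,
                                    value,
                                )
                            else:
                                fpkm, fpkm_raw = parsed, raw
                else:
                    extras.append((name, value))
            if not gene_id and not label:
                logger.warning("line %d: neither gene ID nor label, skipped", lineno)
                continue
            records.append(
                ExpressionRecord(
                    gene_id=gene_id,
                    label=label,
                    transcript_id=transcript_id,
                    fpkm=fpkm,
                    fpkm_raw=fpkm_raw,
                    extra=tuple(extras),
                )
            )
        return records
    finally:
        if close:
            handle.close()


_TRACKING_REQUIRED = ("tracking_id", "gene_id", "gene_short_name", "FPKM")


def read_cufflinks_tracking(source) -> list[ExpressionRecord]:
    """Adapter for the Cufflinks ``*.fpkm_tracking`` dialect.

    Works for both ``isoforms.fpkm_tracking`` (tracking_id is the
    transcript) and ``genes.fpkm_tracking`` (tracking_id equals the
    gene, so no transcript is recorded). The Cufflinks missing token
    ``-`` maps to an empty field.
    """
    handle, close = _open_text(source)
    try:
        header_line = handle.readline().rstrip("\n")
        header = header_line.split("\t")
        missing = [c for c in _TRACKING_REQUIRED if c not in header]
        if missing:
            raise SchemaError(
                "not a Cufflinks fpkm_tracking header; expected columns "
                f"{', '.join(_TRACKING_REQUIRED)} (missing: {', '.join(missing)})"
            )
        idx = {name: i for i, name in enumerate(header)}
        records: list[ExpressionRecord] = []
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                fields = fields + [""] * (len(header) - len(fields))
            tracking = _clean(fields[idx["tracking_id"]])
            gene_id = _clean(fields[idx["gene_id"]])
            label = _clean(fields[idx["gene_short_name"]])
            raw = _clean(fields[idx["FPKM"]])
            fpkm = None
            fpkm_raw = None
            if raw:
                try:
                    fpkm = float(raw)
                    fpkm_raw = raw
                except ValueError:
                    logger.warning("line %d: non-numeric FPKM %r", lineno, raw)
            extras = tuple(
                (name, fields[i])
                for name, i in ((n, idx[n]) for n in header)
                if name not in ("tracking_id", "gene_id", "gene_short_name", "FPKM")
            )
            records.append(
                ExpressionRecord(
                    gene_id=gene_id,
                    label=label,
                    transcript_id=tracking if tracking != gene_id else None,
                    fpkm=fpkm,
                    fpkm_raw=fpkm_raw,
                    extra=extras,
                )
            )
        return records
    finally:
        if close:
            handle.close()


def annotate_records(
    records: Sequence[ExpressionRecord],
    store: XrefStore,
    microarray: Mapping[str, float] | None = None,
) -> list[AnnotatedRecord]:
    """Associate every record with probe sets, preserving order.

    When a microarray intensity table is attached, each annotated row
    carries the intensity of its representative probe set; the
    representative choice itself is intensity-aware. Unmapped records
    flow through with an empty association.
    """
    out: list[AnnotatedRecord] = []
    cache: dict[tuple[str, str], AssociationResult] = {}
    for record in records:
        key = (record.gene_id, record.label)
        assoc = cache.get(key)
        if assoc is None:
            assoc = associate(
                store,
                AssociationQuery(
                    ensembl_gene_id=record.gene_id or None,
                    label=record.label or None,
                ),
                microarray,
            )
            cache[key] = assoc
        rep = assoc.representative_probe_set_id
        intensity = None
        if microarray is not None and rep is not None:
            intensity = microarray.get(rep)
        out.append(
            AnnotatedRecord(
                record=record,
                association=assoc,
                microarray_expression=intensity,
                cytoband=store.cytoband_for_probe(rep) if rep else None,
            )
        )
    return out


ANNOTATION_COLUMNS = (
    "probe_set_ids",
    "representative_probe_set_id",
    "association_method",
    "cytoband",
    "microarray_expression",
)


def write_annotated_table(records: Sequence[AnnotatedRecord], sink) -> None:
    """Write the annotated table as TSV.

    Column order: gene_id, label, transcript_id, FPKM, the original
    extra columns in input order, then the five annotation columns.
    FPKM is echoed verbatim as read; absent values are empty cells.
    Multiple probe sets are ``///``-joined in one cell.
    """
    if hasattr(sink, "write"):
        handle, close = sink, False
    else:
        handle, close = open(sink, "wt", encoding="utf-8"), True
    try:
        extra_names: list[str] = []
        for rec in records:
            for name, _ in rec.record.extra:
                if name not in extra_names:
                    extra_names.append(name)
        header = ["gene_id", "label", "transcript_id", "FPKM", *extra_names,
                  *ANNOTATION_COLUMNS]
        handle.write("\t".join(header) + "\n")
        for rec in records:
            r = rec.record
            row = [
                r.gene_id,
                r.label,
                r.transcript_id or "",
                r.fpkm_raw or "",
                *[r.extra_value(name) or "" for name in extra_names],
                PROBE_JOIN.join(rec.association.probe_set_ids),
                rec.association.representative_probe_set_id or "",
                rec.association.method.value,
                rec.cytoband or "",
                "" if rec.microarray_expression is None else repr(rec.microarray_expression),
            ]
            handle.write("\t".join(row) + "\n")
    finally:
        if close:
            handle.close()


def read_annotated_table(source) -> list[AnnotatedRecord]:
    """Re-read a table written by :func:`write_annotated_table`."""
    handle, close = _open_text(source)
    try:
        header = handle.readline().rstrip("\n").split("\t")
        n_extra = len(header) - 4 - len(ANNOTATION_COLUMNS)
        if n_extra < 0:
            raise SchemaError("not an annotated table: too few columns")
        extra_names = header[4 : 4 + n_extra]
        out: list[AnnotatedRecord] = []
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            fields += [""] * (len(header) - len(fields))
            gene_id, label, transcript, fpkm_raw = fields[:4]
            extras = tuple(zip(extra_names, fields[4 : 4 + n_extra]))
            probes_cell, rep, method, cytoband, intensity = fields[4 + n_extra :][:5]
            probes = tuple(p for p in probes_cell.split(PROBE_JOIN) if p)
            out.append(
                AnnotatedRecord(
                    record=ExpressionRecord(
                        gene_id=gene_id,
                        label=label,
                        transcript_id=transcript or None,
                        fpkm=float(fpkm_raw) if fpkm_raw else None,
                        fpkm_raw=fpkm_raw or None,
                        extra=extras,
                    ),
                    association=AssociationResult(
                        probe_set_ids=probes,
                        representative_probe_set_id=rep or None,
                        method=Method(method) if method else Method.UNMAPPED,
                    ),
                    microarray_expression=float(intensity) if intensity else None,
                    cytoband=cytoband or None,
                )
            )
        return out
    finally:
        if close:
            handle.close()
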