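"""Parsers for the four annotation source dialects.

Four public annotation exports feed the cross-reference store:

* the Affymetrix NetAffx annotation CSV for the HG-U133_Plus_2 array
  (quoted CSV, ``#`` comment header, `` /// `` multi-value cells,
  ``---`` missing token);
* an Ensembl BioMart TSV pairing Ensembl gene IDs with HG-U133 Plus 2
  probe sets;
* an Ensembl GTF, from which one locus envelope per gene is derived;
* the NCBI ``gene2accession`` and ``gene_info`` TSVs (``-`` missing
  token, ``|``-separated synonyms), filtered to one taxon.

All parsers are pure (same bytes in, same rows out), accept file paths
or open text handles, and transparently decompress ``.gz`` paths.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .errors import ParseError, SchemaError

logger = logging.getLogger(__name__)

AFFY_MISSING = "---"
AFFY_DELIM = " /// "
NCBI_MISSING = "-"

HUMAN_TAX_ID = 9606

_VERSION_RE = re.compile(r"\.(\d+)$")


@dataclass(frozen=True)
class AffyAnnotationRow:
    """One probe set's cross references from the NetAffx annotation CSV."""

    probe_set_id: str
    gene_symbols: tuple[str, ...] = ()
    genbank_accessions: tuple[str, ...] = ()
    entrez_gene_ids: tuple[int, ...] = ()
    ensembl_gene_ids: tuple[str, ...] = ()
    cytoband: str | None = None


@dataclass(frozen=True)
class BioMartPair:
    """An (Ensembl gene, Affymetrix probe set) pair from a BioMart export."""

    ensembl_gene_id: str
    probe_set_id: str


@dataclass(frozen=True)
class GeneLocus:
    """A gene's chromosomal envelope, 1-based inclusive as in GTF."""

    ensembl_gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_name: str | None = None


@dataclass(frozen=True)
class NcbiAccessionLink:
    """A (Entrez gene, RNA accession) link from gene2accession."""

    entrez_gene_id: int
    accession: str
    tax_id: int


@dataclass(frozen=True)
class NcbiGeneInfo:
    """An Entrez gene's primary symbol and synonyms from gene_info."""

    entrez_gene_id: int
    symbol: str
    synonyms: tuple[str, ...] = ()


def strip_accession_version(accession: str) -> str:
    """Drop a trailing ``.N`` version suffix when N is all digits.

    ``NM_012242.4`` becomes ``NM_012242``; identifiers whose final
    dot-suffix is not purely numeric are returned unchanged.
    """
    return _VERSION_RE.sub("", accession)


def _open_text(source) -> tuple[TextIO, bool]:
    """Return (handle, should_close). Accepts paths, str paths, handles."""
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8"), True
    return open(path, "rt", encoding="utf-8"), True


def _split_multi(cell: str) -> list[str]:
    """Split a NetAffx multi-value cell, dropping missing tokens."""
    cell = cell.strip()
    if not cell or cell == AFFY_MISSING:
        return []
    return [part.strip() for part in cell.split(AFFY_DELIM.strip()) if part.strip()]


def parse_affy_annotation(source) -> list[AffyAnnotationRow]:
    """Parse a NetAffx annotation CSV into one row per probe set.

    Leading ``#`` lines are comments; the first non-comment line is the
    header. Multi-valued cells are split on `` /// `` and trimmed;
    ``---`` cells yield empty lists; accession versions are stripped.
    Accessions are taken from both the "Representative Public ID" and
    "RefSeq Transcript ID" columns when present.
    """
    handle, close = _open_text(source)
    try:
        rows: list[AffyAnnotationRow] = []
        lineno = 0
        header: list[str] | None = None
        reader = csv.reader(handle)
        for fields in reader:
            lineno = reader.line_num
            if not fields or (fields[0].startswith("#") and header is None):
                continue
            if header is None:
                header = [h.strip() for h in fields]
                idx = {h.lower(): i for i, h in enumerate(header)}
                try:
                    i_probe = idx["probe set id"]
                except KeyError:
                    raise SchemaError(
                        "NetAffx header lacks a 'Probe Set ID' column"
                    ) from None
                i_symbol = idx.get("gene symbol")
                i_rep = idx.get("representative public id")
                i_refseq = idx.get("refseq transcript id")
                i_entrez = idx.get("entrez gene")
                i_ensembl = idx.get("ensembl")
                i_cyto = idx.get("chromosomal location")
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, found {len(fields)}", lineno
                )
            probe = fields[i_probe].strip()
            if not probe:
                raise ParseError("empty probe set ID", lineno)
            accessions: list[str] = []
            for i_col in (i_rep, i_refseq):
                if i_col is not None:
                    accessions.extend(
                        strip_accession_version(a) for a in _split_multi(fields[i_col])
                    )
            entrez: list[int] = []
            if i_entrez is not None:
                for tok in _split_multi(fields[i_entrez]):
                    try:
                        entrez.append(int(tok))
                    except ValueError:
                        raise ParseError(
                            f"non-integer Entrez gene ID {tok!r}", lineno
                        ) from None
            cytoband = None
            if i_cyto is not None:
                cell = fields[i_cyto].strip()
                if cell and cell != AFFY_MISSING:
                    cytoband = cell
            rows.append(
                AffyAnnotationRow(
                    probe_set_id=probe,
                    gene_symbols=tuple(
                        _split_multi(fields[i_symbol]) if i_symbol is not None else ()
                    ),
                    genbank_accessions=tuple(dict.fromkeys(accessions)),
                    entrez_gene_ids=tuple(dict.fromkeys(entrez)),
                    ensembl_gene_ids=tuple(
                        _split_multi(fields[i_ensembl]) if i_ensembl is not None else ()
                    ),
                    cytoband=cytoband,
                )
            )
        if header is None:
            raise SchemaError("NetAffx file has no header line")
        return rows
    finally:
        if close:
            handle.close()


def parse_biomart_export(source) -> list[BioMartPair]:
    """Parse a BioMart TSV of (Ensembl gene ID, probe set) pairs.

    Rows with an empty probe set field are dropped; duplicates collapse
    to one pair, preserving first-seen order.
    """
    handle, close = _open_text(source)
    try:
        seen: dict[BioMartPair, None] = {}
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SchemaError(
                    f"BioMart export needs >=2 columns, found {len(fields)} "
                    f"on line {lineno}"
                )
            if lineno == 1 and not fields[0].startswith("ENS"):
                continue  # header line
            gene, probe = fields[0].strip(), fields[1].strip()
            if not probe:
                continue
            if not gene:
                raise ParseError("empty Ensembl gene ID", lineno)
            seen.setdefault(BioMartPair(gene, probe))
        return list(seen)
    finally:
        if close:
            handle.close()


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    """Parse a GTF attribute string into a key->value dict (first wins)."""
    out: dict[str, str] = {}
    for key, value in _GTF_ATTR_RE.findall(attr_field):
        out.setdefault(key, value)
    return out


def parse_ensembl_gtf(source) -> list[GeneLocus]:
    """Derive one locus envelope per gene from an Ensembl GTF.

    For each distinct ``gene_id`` the envelope is the min feature start
    and max feature end over all of that gene's features, 1-based
    inclusive. Strand and gene_name come from the first feature seen;
    a gene whose features disagree on strand is logged as a warning.
    """
    handle, close = _open_text(source)
    try:
        first: dict[str, GeneLocus] = {}
        mixed_strand: set[str] = set()
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"GTF feature line has {len(fields)} columns, expected 9", lineno
                )
            chrom, _, _, start_s, end_s, _, strand, _, attrs = fields[:9]
            attr = parse_gtf_attributes(attrs)
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise ParseError("feature lacks a gene_id attribute", lineno)
            start, end = int(start_s), int(end_s)
            prev = first.get(gene_id)
            if prev is None:
                first[gene_id] = GeneLocus(
                    ensembl_gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_name=attr.get("gene_name"),
                )
            else:
                if strand != prev.strand and gene_id not in mixed_strand:
                    mixed_strand.add(gene_id)
                    logger.warning(
                        "gene %s has features on both strands; keeping %s",
                        gene_id,
                        prev.strand,
                    )
                first[gene_id] = GeneLocus(
                    ensembl_gene_id=gene_id,
                    chrom=prev.chrom,
                    start=min(prev.start, start),
                    end=max(prev.end, end),
                    strand=prev.strand,
                    gene_name=prev.gene_name or attr.get("gene_name"),
                )
        return list(first.values())
    finally:
        if close:
            handle.close()


def _ncbi_rows(handle) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields and not fields[0].strip().isdigit():
            continue  # header without leading '#'
        yield lineno, fields


def parse_gene2accession(
    source, tax_filter: int = HUMAN_TAX_ID
) -> list[NcbiAccessionLink]:
    """Parse NCBI gene2accession, keeping rows for one taxon.

    The RNA accession (column 4) is version-stripped; rows whose
    accession is the ``-`` missing token are dropped.
    """
    handle, close = _open_text(source)
    try:
        links: list[NcbiAccessionLink] = []
        for lineno, fields in _ncbi_rows(handle):
            if len(fields) < 4:
                raise ParseError("gene2accession row has <4 columns", lineno)
            try:
                tax_id = int(fields[0])
                gene_id = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"non-integer tax_id/GeneID in {fields[:2]!r}", lineno
                ) from None
            if tax_id != tax_filter:
                continue
            accession = fields[3].strip()
            if not accession or accession == NCBI_MISSING:
                continue
            links.append(
                NcbiAccessionLink(
                    entrez_gene_id=gene_id,
                    accession=strip_accession_version(accession),
                    tax_id=tax_id,
                )
            )
        return links
    finally:
        if close:
            handle.close()


def parse_gene_info(source, tax_filter: int = HUMAN_TAX_ID) -> list[NcbiGeneInfo]:
    """Parse NCBI gene_info, keeping one taxon's symbols and synonyms."""
    handle, close = _open_text(source)
    try:
        infos: list[NcbiGeneInfo] = []
        for lineno, fields in _ncbi_rows(handle):
            if len(fields) < 5:
                raise ParseError("gene_info row has <5 columns", lineno)
            try:
                tax_id = int(fields[0])
                gene_id = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"non-integer tax_id/GeneID in {fields[:2]!r}", lineno
                ) from None
            if tax_id != tax_filter:
                continue
            symbol = fields[2].strip()
            if not symbol or symbol == NCBI_MISSING:
                raise ParseError("gene_info row lacks a symbol", lineno)
            syn_cell = fields[4].strip()
            synonyms: tuple[str, ...] = ()
            if syn_cell and syn_cell != NCBI_MISSING:
                synonyms = tuple(s.strip() for s in syn_cell.split("|") if s.strip())
            infos.append(
                NcbiGeneInfo(
                    entrez_gene_id=gene_id, symbol=symbol, synonyms=synonyms
                )
            )
        return infos
    finally:
        if close:
            handle.close()
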