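"""Embedded relational store of identifier look-up tables.

The store holds the cross references needed to resolve RNA-seq gene
records back to Affymetrix HG-U133 Plus 2 probe sets: probe set to
Ensembl gene, probe set to Entrez gene, probe set to symbol, GenBank
accession to Entrez/Ensembl gene, symbol to Ensembl/Entrez gene, plus
one chromosomal locus envelope per Ensembl gene. Each relation row
carries a provenance tag naming the source file(s) it came from
(``affy``, ``biomart``, ``ncbi``, ``gtf``).

It is backed by a single sqlite database (in-memory by default, or a
single file on disk), built once from the ingested annotation rows and
queried read-only afterwards. Symbols are stored case-folded to upper
case; accessions are stored version-stripped.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation_ingest import (
    AffyAnnotationRow,
    BioMartPair,
    GeneLocus,
    NcbiAccessionLink,
    NcbiGeneInfo,
    strip_accession_version,
)
from .errors import BuildError, ProbelinkError

logger = logging.getLogger(__name__)

_SCHEMA = """
CREATE TABLE probe_ensembl (probe_set_id TEXT, ensembl_gene_id TEXT,
    provenance TEXT, PRIMARY KEY (probe_set_id, ensembl_gene_id));
CREATE TABLE probe_entrez (probe_set_id TEXT, entrez_gene_id INTEGER,
    provenance TEXT, PRIMARY KEY (probe_set_id, entrez_gene_id));
CREATE TABLE probe_symbol (probe_set_id TEXT, symbol TEXT,
    provenance TEXT, PRIMARY KEY (probe_set_id, symbol));
CREATE TABLE probe_cytoband (probe_set_id TEXT PRIMARY KEY, cytoband TEXT);
CREATE TABLE accession_entrez (accession TEXT, entrez_gene_id INTEGER,
    provenance TEXT, PRIMARY KEY (accession, entrez_gene_id));
CREATE TABLE accession_ensembl (accession TEXT, ensembl_gene_id TEXT,
    provenance TEXT, PRIMARY KEY (accession, ensembl_gene_id));
CREATE TABLE symbol_ensembl (symbol TEXT, ensembl_gene_id TEXT,
    provenance TEXT, PRIMARY KEY (symbol, ensembl_gene_id));
CREATE TABLE symbol_entrez (symbol TEXT, entrez_gene_id INTEGER,
    is_synonym INTEGER, provenance TEXT,
    PRIMARY KEY (symbol, entrez_gene_id, is_synonym));
CREATE TABLE entrez_symbol (entrez_gene_id INTEGER PRIMARY KEY, symbol TEXT);
CREATE TABLE gene_locus (ensembl_gene_id TEXT PRIMARY KEY, chrom TEXT,
    start INTEGER, end INTEGER, strand TEXT, gene_name TEXT);
CREATE INDEX ix_pe_gene ON probe_ensembl (ensembl_gene_id);
CREATE INDEX ix_pz_gene ON probe_entrez (entrez_gene_id);
CREATE INDEX ix_ps_sym ON probe_symbol (symbol);
CREATE INDEX ix_locus ON gene_locus (chrom, start, end);
"""

# Probe set suffix classes, most specific first; plain "_at" designs are
# gene-unique, "_s_at"/"_x_at" cross-hybridize and rank lower.
_SUFFIX_ORDER = ("_s_at", "_x_at", "_at")


def probe_suffix_rank(probe_set_id: str) -> int:
    """Rank a probe set by design suffix: _at < _s_at < _x_at < other."""
    if probe_set_id.endswith("_s_at"):
        return 1
    if probe_set_id.endswith("_x_at"):
        return 2
    if probe_set_id.endswith("_at"):
        return 0
    return 3


def probe_sort_key(probe_set_id: str) -> tuple[int, str]:
    return (probe_suffix_rank(probe_set_id), probe_set_id)


class XrefStore:
    """Read-only query surface over the built look-up tables."""

    def __init__(self, connection: sqlite3.Connection):
        self._conn = connection

    # -- construction ------------------------------------------------

    @classmethod
    def open(cls, path: str | Path) -> "XrefStore":
        """Open a previously persisted store file."""
        conn = sqlite3.connect(str(path))
        return cls(conn)

    def save(self, path: str | Path) -> None:
        """Persist the store as a single sqlite file."""
        dest = sqlite3.connect(str(path))
        with dest:
            self._conn.backup(dest)
        dest.close()

    def close(self) -> None:
        self._conn.close()

    # -- queries -----------------------------------------------------

    def _column(self, sql: str, params: tuple) -> list:
        return [row[0] for row in self._conn.execute(sql, params)]

    def probe_sets_for_ensembl(self, gene_id: str) -> list[str]:
        """Probe sets mapped to an Ensembl gene (Affy and BioMart union)."""
        probes = self._column(
            "SELECT probe_set_id FROM probe_ensembl WHERE ensembl_gene_id = ?",
            (gene_id,),
        )
        return sorted(probes, key=probe_sort_key)

    def probe_sets_for_entrez(self, entrez_id: int) -> list[str]:
        probes = self._column(
            "SELECT probe_set_id FROM probe_entrez WHERE entrez_gene_id = ?",
            (entrez_id,),
        )
        return sorted(probes, key=probe_sort_key)

    def probe_sets_for_symbol(self, symbol: str) -> list[str]:
        """Probe sets whose NetAffx row lists this gene symbol."""
        probes = self._column(
            "SELECT probe_set_id FROM probe_symbol WHERE symbol = ?",
            (symbol.upper(),),
        )
        return sorted(probes, key=probe_sort_key)

    def entrez_for_accession(self, accession: str) -> list[int]:
        return sorted(
            self._column(
                "SELECT entrez_gene_id FROM accession_entrez WHERE accession = ?",
                (strip_accession_version(accession),),
            )
        )

    def ensembl_for_accession(self, accession: str) -> list[str]:
        return sorted(
            self._column(
                "SELECT ensembl_gene_id FROM accession_ensembl WHERE accession = ?",
                (strip_accession_version(accession),),
            )
        )

    def ensembl_for_symbol(self, symbol: str) -> list[str]:
        return sorted(
            self._column(
                "SELECT ensembl_gene_id FROM symbol_ensembl WHERE symbol = ?",
                (symbol.upper(),),
            )
        )

    def entrez_for_symbol(self, symbol: str) -> list[int]:
        """Entrez IDs for a symbol; NCBI synonyms only on primary miss."""
        primary = self._column(
            "SELECT entrez_gene_id FROM symbol_entrez "
            "WHERE symbol = ? AND is_synonym = 0",
            (symbol.upper(),),
        )
        if primary:
            return sorted(primary)
        return sorted(
            self._column(
                "SELECT entrez_gene_id FROM symbol_entrez "
                "WHERE symbol = ? AND is_synonym = 1",
                (symbol.upper(),),
            )
        )

    def symbol_for_entrez(self, entrez_id: int) -> str | None:
        row = self._conn.execute(
            "SELECT symbol FROM entrez_symbol WHERE entrez_gene_id = ?",
            (entrez_id,),
        ).fetchone()
        return row[0] if row else None

    def cytoband_for_probe(self, probe_set_id: str) -> str | None:
        row = self._conn.execute(
            "SELECT cytoband FROM probe_cytoband WHERE probe_set_id = ?",
            (probe_set_id,),
        ).fetchone()
        return row[0] if row else None

    def locus_for_gene(self, gene_id: str) -> GeneLocus | None:
        row = self._conn.execute(
            "SELECT ensembl_gene_id, chrom, start, end, strand, gene_name "
            "FROM gene_locus WHERE ensembl_gene_id = ?",
            (gene_id,),
        ).fetchone()
        return GeneLocus(*row) if row else None

    def all_loci(self) -> list[GeneLocus]:
        rows = self._conn.execute(
            "SELECT ensembl_gene_id, chrom, start, end, strand, gene_name "
            "FROM gene_locus"
        ).fetchall()
        return [GeneLocus(*row) for row in rows]

    def genes_in_locus(self, chrom: str, start: int, end: int) -> list[GeneLocus]:
        """Genes whose closed interval overlaps [start, end] by >=1 base."""
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        rows = self._conn.execute(
            "SELECT ensembl_gene_id, chrom, start, end, strand, gene_name "
            "FROM gene_locus WHERE chrom = ? AND start <= ? AND end >= ? "
            "ORDER BY start, ensembl_gene_id",
            (chrom, end, start),
        ).fetchall()
        return [GeneLocus(*row) for row in rows]

    def genes_for_cytoband(self, cytoband: str) -> list[str]:
        """Ensembl genes whose probe sets carry this cytoband annotation."""
        return sorted(
            self._column(
                "SELECT DISTINCT pe.ensembl_gene_id FROM probe_cytoband pc "
                "JOIN probe_ensembl pe ON pe.probe_set_id = pc.probe_set_id "
                "WHERE pc.cytoband = ? COLLATE NOCASE",
                (cytoband,),
            )
        )

    def probe_set_universe(self) -> set[str]:
        probes = set(self._column("SELECT DISTINCT probe_set_id FROM probe_ensembl", ()))
        probes |= set(self._column("SELECT DISTINCT probe_set_id FROM probe_entrez", ()))
        probes |= set(self._column("SELECT DISTINCT probe_set_id FROM probe_symbol", ()))
        probes |= set(
            self._column("SELECT DISTINCT probe_set_id FROM probe_cytoband", ())
        )
        return probes

    def table_counts(self) -> dict[str, int]:
        tables = [
            "probe_ensembl",
            "probe_entrez",
            "probe_symbol",
            "probe_cytoband",
            "accession_entrez",
            "accession_ensembl",
            "symbol_ensembl",
            "symbol_entrez",
            "gene_locus",
        ]
        return {
            t: self._conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
            for t in tables
        }


def _merge_provenance(existing: str | None, new: str) -> str:
    tags = set(new.split(","))
    if existing:
        tags |= set(existing.split(","))
    return ",".join(sorted(tags))


class _RelationBuffer:
    """Accumulates deduplicated relation rows with merged provenance."""

    def __init__(self):
        self.rows: dict[tuple, str] = {}

    def add(self, key: tuple, provenance: str) -> None:
        self.rows[key] = _merge_provenance(self.rows.get(key), provenance)


def build_store(
    affy_rows: Sequence[AffyAnnotationRow] = (),
    biomart_pairs: Sequence[BioMartPair] = (),
    ncbi_links: Sequence[NcbiAccessionLink] = (),
    ncbi_info: Sequence[NcbiGeneInfo] = (),
    gene_loci: Sequence[GeneLocus] = (),
    path: str | Path | None = None,
) -> XrefStore:
    """Build the look-up-table store from ingested annotation rows.

    Relations are deduplicated (a pair present in several sources keeps
    a merged provenance tag such as ``affy,biomart``) and indexed on
    every lookup key. A build summary of per-table row counts is
    logged as key=value lines.

    Raises :class:`BuildError` when no probe sets were supplied at all.
    """
    if not affy_rows and not biomart_pairs:
        raise BuildError("empty probe-set universe: no Affy rows and no BioMart pairs")

    conn = sqlite3.connect(str(path) if path is not None else ":memory:")
    conn.executescript(_SCHEMA)

    probe_ensembl = _RelationBuffer()
    probe_entrez = _RelationBuffer()
    probe_symbol = _RelationBuffer()
    accession_entrez = _RelationBuffer()
    accession_ensembl = _RelationBuffer()
    symbol_ensembl = _RelationBuffer()
    symbol_entrez: dict[tuple, str] = {}
    cytobands: dict[str, str] = {}
    entrez_symbol: dict[int, str] = {}

    for row in affy_rows:
        for ensg in row.ensembl_gene_ids:
            probe_ensembl.add((row.probe_set_id, ensg), "affy")
        for eg in row.entrez_gene_ids:
            probe_entrez.add((row.probe_set_id, eg), "affy")
        for sym in row.gene_symbols:
            probe_symbol.add((row.probe_set_id, sym.upper()), "affy")
            for ensg in row.ensembl_gene_ids:
                symbol_ensembl.add((sym.upper(), ensg), "affy")
        for acc in row.genbank_accessions:
            for eg in row.entrez_gene_ids:
                accession_entrez.add((acc, eg), "affy")
            for ensg in row.ensembl_gene_ids:
                accession_ensembl.add((acc, ensg), "affy")
        if row.cytoband:
            cytobands.setdefault(row.probe_set_id, row.cytoband)

    for pair in biomart_pairs:
        probe_ensembl.add((pair.probe_set_id, pair.ensembl_gene_id), "biomart")

    for link in ncbi_links:
        accession_entrez.add((link.accession, link.entrez_gene_id), "ncbi")

    for info in ncbi_info:
        symbol_entrez.setdefault((info.symbol.upper(), info.entrez_gene_id, 0), "ncbi")
        entrez_symbol.setdefault(info.entrez_gene_id, info.symbol)
        for syn in info.synonyms:
            symbol_entrez.setdefault((syn.upper(), info.entrez_gene_id, 1), "ncbi")

    loci: dict[str, GeneLocus] = {}
    for locus in gene_loci:
        loci.setdefault(locus.ensembl_gene_id, locus)
        if locus.gene_name:
            symbol_ensembl.add((locus.gene_name.upper(), locus.ensembl_gene_id), "gtf")

    with conn:
        conn.executemany(
            "INSERT INTO probe_ensembl VALUES (?,?,?)",
            [(*k, v) for k, v in probe_ensembl.rows.items()],
        )
        conn.executemany(
            "INSERT INTO probe_entrez VALUES (?,?,?)",
            [(*k, v) for k, v in probe_entrez.rows.items()],
        )
        conn.executemany(
            "INSERT INTO probe_symbol VALUES (?,?,?)",
            [(*k, v) for k, v in probe_symbol.rows.items()],
        )
        conn.executemany(
            "INSERT INTO probe_cytoband VALUES (?,?)", list(cytobands.items())
        )
        conn.executemany(
            "INSERT INTO accession_entrez VALUES (?,?,?)",
            [(*k, v) for k, v in accession_entrez.rows.items()],
        )
        conn.executemany(
            "INSERT INTO accession_ensembl VALUES (?,?,?)",
            [(*k, v) for k, v in accession_ensembl.rows.items()],
        )
        conn.executemany(
            "INSERT INTO symbol_ensembl VALUES (?,?,?)",
            [(*k, v) for k, v in symbol_ensembl.rows.items()],
        )
        conn.executemany(
            "INSERT INTO symbol_entrez VALUES (?,?,?,?)",
            [(*k, v) for k, v in symbol_entrez.items()],
        )
        conn.executemany(
            "INSERT INTO entrez_symbol VALUES (?,?)", list(entrez_symbol.items())
        )
        conn.executemany(
            "INSERT INTO gene_locus VALUES (?,?,?,?,?,?)",
            [
                (l.ensembl_gene_id, l.chrom, l.start, l.end, l.strand, l.gene_name)
                for l in loci.values()
            ],
        )

    store = XrefStore(conn)
    for table, count in store.table_counts().items():
        logger.info("build_summary table=%s rows=%d", table, count)
    return store
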