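"""Gene-set loading and biologically directed filtering.

A gene set is a named member list whose members may be Affymetrix
probe set IDs, gene symbols, or Ensembl gene IDs; the kind of each
member is auto-detected. Filtering reduces an annotated expression
table to records matching the set on any of the three member kinds,
so a record whose array association failed can still match by symbol
or Ensembl ID.

A small catalog ships with the package: the 8-gene multiple-myeloma
key-gene list (``MM8``: CCND1, CCND3, DKK1, FGFR3, MAF, MAFB, NFKB1,
WHSC1) and probe-set stand-ins for the GEP-70 and GEP-80 prognostic
risk signatures. The true GEP membership is published elsewhere and
is licensing-sensitive, so the packaged lists are clearly synthetic
stand-ins (see ``catalog/README``-style headers in each file); users
point ``catalog_dir`` at their own lists for real analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CatalogError
from .expression_io import AnnotatedRecord

_PROBE_RE = re.compile(r"_at$")
# gene-ID members: Ensembl genes or Cufflinks novel gene IDs
_ENSEMBL_RE = re.compile(r"^(ENSG\d+|CUFF\.\d+)$")


@dataclass(frozen=True)
class GeneSet:
    name: str
    probe_set_members: frozenset[str] = frozenset()
    symbol_members: frozenset[str] = frozenset()
    ensembl_members: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return (
            len(self.probe_set_members)
            + len(self.symbol_members)
            + len(self.ensembl_members)
        )


def _classify_members(name: str, members: Iterable[str]) -> GeneSet:
    probes: set[str] = set()
    symbols: set[str] = set()
    ensembl: set[str] = set()
    for member in members:
        member = member.strip()
        if not member:
            continue
        if _PROBE_RE.search(member):
            probes.add(member)
        elif _ENSEMBL_RE.match(member):
            ensembl.add(member)
        else:
            symbols.add(member.upper())
    if not probes and not symbols and not ensembl:
        raise CatalogError(f"gene set {name!r} has no members")
    return GeneSet(
        name=name,
        probe_set_members=frozenset(probes),
        symbol_members=frozenset(symbols),
        ensembl_members=frozenset(ensembl),
    )


def _catalog_names(catalog_dir: Path | None) -> dict[str, Path]:
    if catalog_dir is None:
        catalog_dir = Path(str(resources.files("probelink") / "catalog"))
    return {p.stem: p for p in sorted(catalog_dir.glob("*.txt"))}


def load_gene_set(
    source: str | Path,
    catalog_dir: str | Path | None = None,
) -> GeneSet:
    """Load a gene set from a member-list file or the packaged catalog.

    ``source`` is first tried as a catalog name (``MM8``, ``GEP-70``,
    ``GEP-80`` by default), then as a path to a one-member-per-line
    text file (``#`` comments allowed). Members are de-duplicated and
    symbols case-folded to upper case.
    """
    catalog = _catalog_names(Path(catalog_dir) if catalog_dir else None)
    if str(source) in catalog:
        path = catalog[str(source)]
        name = str(source)
    else:
        path = Path(source)
        if not path.exists():
            raise CatalogError(
                f"unknown gene set {source!r}; available catalog sets: "
                + ", ".join(sorted(catalog))
            )
        name = path.stem
    members = [
        line.strip()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not members:
        raise CatalogError(f"gene set file {path} is empty")
    return _classify_members(name, members)


def record_matches(record: AnnotatedRecord, gene_set: GeneSet) -> bool:
    if any(p in gene_set.probe_set_members for p in record.association.probe_set_ids):
        return True
    if record.record.label and record.record.label.upper() in gene_set.symbol_members:
        return True
    return record.record.gene_id in gene_set.ensembl_members


def filter_records(
    records: Sequence[AnnotatedRecord], gene_set: GeneSet
) -> list[AnnotatedRecord]:
    """Keep records matching the set by probe set, symbol or gene ID."""
    return [r for r in records if record_matches(r, gene_set)]


@dataclass(frozen=True)
class FilterReport:
    gene_set: str
    input_records: int
    kept_records: int
    distinct_genes_kept: int
    members_not_observed: int


def _record_gene_key(record: AnnotatedRecord) -> str:
    return record.record.gene_id or record.record.label.upper()


def summarize_filter(
    records_in: Sequence[AnnotatedRecord],
    records_out: Sequence[AnnotatedRecord],
    gene_set: GeneSet,
) -> FilterReport:
    """Summarize a filter run: counts kept and members never observed."""
    matched_members: set[str] = set()
    for record in records_out:
        for probe in record.association.probe_set_ids:
            if probe in gene_set.probe_set_members:
                matched_members.add(probe)
        label = record.record.label.upper()
        if label in gene_set.symbol_members:
            matched_members.add(label)
        if record.record.gene_id in gene_set.ensembl_members:
            matched_members.add(record.record.gene_id)
    return FilterReport(
        gene_set=gene_set.name,
        input_records=len(records_in),
        kept_records=len(records_out),
        distinct_genes_kept=len({_record_gene_key(r) for r in records_out}),
        members_not_observed=len(gene_set) - len(matched_members),
    )
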