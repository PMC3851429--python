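"""Identifier-resolution cascade from RNA-seq records to probe sets.

Each input record carries an Ensembl gene ID (when known) and a label
that may be a gene symbol or a GenBank accession. Resolution proceeds
through a fixed cascade, stopping at the first branch that yields a
non-empty probe set list:

1. direct — Ensembl gene ID to probe set (union of the NetAffx file's
   Ensembl column and the BioMart pairs); failing that, the label as a
   symbol against the NetAffx symbol column;
2. indirect, accession route — label as a version-stripped accession,
   to Entrez gene via NCBI gene2accession, then Entrez to probe set;
   the resolved symbol is filled in from gene_info for completeness;
3. accession to Ensembl gene, then Ensembl gene to probe set;
4. label as symbol to Ensembl gene, then to probe set;
5. label as symbol to Entrez gene, then to probe set;
6. otherwise the record is reported unmapped.

Novel Cufflinks genes (``CUFF.*`` IDs with no usable label) have no
array ancestry and come out unmapped by construction.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .xref_store import XrefStore, probe_sort_key

logger = logging.getLogger(__name__)

# Accession-shaped labels: 1-3 letters, optional underscore, digits
# (NM_012242, BC108917, U12345). Checked after version stripping.
_ACCESSION_RE = re.compile(r"^[A-Z]{1,3}_?\d+$")


class Method(str, enum.Enum):
    """Which cascade branch resolved a query."""

    DIRECT = "direct"
    INDIRECT_ACCESSION_ENTREZ = "indirect_accession_entrez"
    INDIRECT_ACCESSION_ENSEMBL = "indirect_accession_ensembl"
    INDIRECT_SYMBOL_ENSEMBL = "indirect_symbol_ensembl"
    INDIRECT_SYMBOL_ENTREZ = "indirect_symbol_entrez"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class AssociationQuery:
    """One record to resolve: Ensembl gene ID and/or free-form label."""

    ensembl_gene_id: str | None = None
    label: str | None = None

    def __post_init__(self):
        if not self.ensembl_gene_id and not self.label:
            raise ValueError("query needs an Ensembl gene ID or a label")


@dataclass(frozen=True)
class AssociationResult:
    probe_set_ids: tuple[str, ...]
    representative_probe_set_id: str | None
    method: Method
    resolved_symbol: str | None = None
    resolved_ensembl_gene_id: str | None = None


def looks_like_accession(label: str) -> bool:
    """True when a label is accession-shaped (after version stripping)."""
    from .annotation_ingest import strip_accession_version

    return bool(_ACCESSION_RE.match(strip_accession_version(label.strip())))


def choose_representative(
    probe_set_ids: Sequence[str],
    microarray_intensity_by_probe: Mapping[str, float] | None = None,
) -> str:
    """Pick one representative probe set for display.

    With microarray intensities attached, the most intense probe set
    wins (ties broken by suffix rank then lexicographically). Without
    intensities, probe sets rank by design suffix — unique ``_at``
    designs before cross-hybridizing ``_s_at``/``_x_at`` — then
    lexicographically.
    """
    if not probe_set_ids:
        raise ValueError("cannot choose a representative from an empty list")
    if microarray_intensity_by_probe:
        known = [p for p in probe_set_ids if p in microarray_intensity_by_probe]
        if known:
            return min(
                known,
                key=lambda p: (
                    -microarray_intensity_by_probe[p],
                    *probe_sort_key(p),
                ),
            )
    return min(probe_set_ids, key=probe_sort_key)


def associate(
    store: XrefStore,
    query: AssociationQuery,
    intensities: Mapping[str, float] | None = None,
) -> AssociationResult:
    """Resolve one query through the direct/indirect cascade.

    Failures are not errors: an exhausted cascade yields an unmapped
    result with an empty probe set list, and is logged.
    """
    label = (query.label or "").strip()

    def _result(
        probes: Sequence[str],
        method: Method,
        symbol: str | None = None,
        ensembl: str | None = None,
    ) -> AssociationResult:
        ordered = tuple(sorted(set(probes), key=probe_sort_key))
        return AssociationResult(
            probe_set_ids=ordered,
            representative_probe_set_id=choose_representative(ordered, intensities),
            method=method,
            resolved_symbol=symbol,
            resolved_ensembl_gene_id=ensembl,
        )

    # 1. direct: Ensembl gene ID, else label as NetAffx symbol
    if query.ensembl_gene_id:
        probes = store.probe_sets_for_ensembl(query.ensembl_gene_id)
        if probes:
            symbol = label.upper() if label and not looks_like_accession(label) else None
            return _result(
                probes, Method.DIRECT, ensembl=query.ensembl_gene_id, symbol=symbol
            )
    if label:
        probes = store.probe_sets_for_symbol(label)
        if probes:
            return _result(probes, Method.DIRECT, symbol=label.upper())

    if label:
        as_accession = looks_like_accession(label)

        # 2. accession -> Entrez -> probe sets
        if as_accession:
            for entrez in store.entrez_for_accession(label):
                probes = store.probe_sets_for_entrez(entrez)
                if probes:
                    return _result(
                        probes,
                        Method.INDIRECT_ACCESSION_ENTREZ,
                        symbol=store.symbol_for_entrez(entrez),
                    )

            # 3. accession -> Ensembl gene -> probe sets
            for ensembl in store.ensembl_for_accession(label):
                probes = store.probe_sets_for_ensembl(ensembl)
                if probes:
                    locus = store.locus_for_gene(ensembl)
                    return _result(
                        probes,
                        Method.INDIRECT_ACCESSION_ENSEMBL,
                        ensembl=ensembl,
                        symbol=locus.gene_name if locus else None,
                    )

        # 4. symbol -> Ensembl gene -> probe sets
        for ensembl in store.ensembl_for_symbol(label):
            probes = store.probe_sets_for_ensembl(ensembl)
            if probes:
                return _result(
                    probes,
                    Method.INDIRECT_SYMBOL_ENSEMBL,
                    symbol=label.upper(),
                    ensembl=ensembl,
                )

        # 5. symbol -> Entrez gene -> probe sets
        for entrez in store.entrez_for_symbol(label):
            probes = store.probe_sets_for_entrez(entrez)
            if probes:
                return _result(
                    probes,
                    Method.INDIRECT_SYMBOL_ENTREZ,
                    symbol=store.symbol_for_entrez(entrez) or label.upper(),
                )

    logger.info(
        "unmapped ensembl=%s label=%s", query.ensembl_gene_id or "-", label or "-"
    )
    return AssociationResult(
        probe_set_ids=(),
        representative_probe_set_id=None,
        method=Method.UNMAPPED,
        resolved_symbol=None,
        resolved_ensembl_gene_id=None,
    )


def associate_locus(
    store: XrefStore,
    chrom: str,
    start: int,
    end: int,
    intensities: Mapping[str, float] | None = None,
) -> list[AssociationResult]:
    """Associate every gene overlapping a chromosomal interval.

    Genes come back in locus order (start position, then gene ID), each
    resolved through :func:`associate` by its Ensembl gene ID.
    """
    results = []
    for locus in store.genes_in_locus(chrom, start, end):
        results.append(
            associate(
                store,
                AssociationQuery(
                    ensembl_gene_id=locus.ensembl_gene_id, label=locus.gene_name
                ),
                intensities,
            )
        )
    return results
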