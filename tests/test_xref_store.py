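"""Look-up-table store: build, dedupe, indexed queries, locus scans."""

import sqlite3

import pytest

from probelink.annotation_ingest import (
    AffyAnnotationRow,
    BioMartPair,
    GeneLocus,
    NcbiAccessionLink,
    NcbiGeneInfo,
)
from probelink.errors import BuildError
from probelink.xref_store import build_store, probe_suffix_rank


@pytest.fixture()
def tiny_store():
    affy = [
        AffyAnnotationRow(
            probe_set_id="204602_at",
            gene_symbols=("DKK1",),
            genbank_accessions=("NM_012242",),
            entrez_gene_ids=(22943,),
            ensembl_gene_ids=("ENSG00000107984",),
            cytoband="chr10q21.1",
        ),
        AffyAnnotationRow(
            probe_set_id="204380_s_at",
            gene_symbols=("FGFR3",),
            ensembl_gene_ids=("ENSG00000068078",),
            cytoband="chr4p16.3",
        ),
        AffyAnnotationRow(
            probe_set_id="1557780_at",
            gene_symbols=("WHSC1",),
            ensembl_gene_ids=("ENSG00000109685",),
            cytoband="chr4p16.3",
        ),
        AffyAnnotationRow(probe_set_id="209239_at", gene_symbols=("NFKB1",)),
    ]
    biomart = [
        BioMartPair("ENSG00000107984", "204602_at"),  # duplicate of affy pair
        BioMartPair("ENSG00000109320", "209239_at"),
        BioMartPair("ENSG00000109320", "209240_x_at"),
    ]
    links = [NcbiAccessionLink(22943, "NM_012242", 9606)]
    info = [NcbiGeneInfo(22943, "DKK1", ("SK", "DKK-1")),
            NcbiGeneInfo(999001, "SK", ())]
    loci = [
        GeneLocus("ENSG00000068078", "chr4", 1795039, 1810599, "+", "FGFR3"),
        GeneLocus("ENSG00000109685", "chr4", 1873151, 1983934, "+", "WHSC1"),
        GeneLocus("ENSG00000107984", "chr10", 54074056, 54077416, "+", "DKK1"),
    ]
    return build_store(affy, biomart, links, info, loci), loci


def test_empty_probe_universe_is_build_error():
    with pytest.raises(BuildError):
        build_store([], [], [], [], [])


def test_probe_ensembl_is_union_of_affy_and_biomart(tiny_store):
    store, _ = tiny_store
    # enumerated by hand over the fixture inputs above
    expected = {
        ("204602_at", "ENSG00000107984"),
        ("204380_s_at", "ENSG00000068078"),
        ("1557780_at", "ENSG00000109685"),
        ("209239_at", "ENSG00000109320"),
        ("209240_x_at", "ENSG00000109320"),
    }
    got = {
        (p, g)
        for g in ("ENSG00000107984", "ENSG00000068078", "ENSG00000109685",
                  "ENSG00000109320")
        for p in store.probe_sets_for_ensembl(g)
    }
    assert got == expected


def test_duplicate_pair_stored_once_with_merged_provenance(tiny_store):
    store, _ = tiny_store
    rows = store._conn.execute(
        "SELECT provenance FROM probe_ensembl "
        "WHERE probe_set_id='204602_at' AND ensembl_gene_id='ENSG00000107984'"
    ).fetchall()
    assert rows == [("affy,biomart",)]


def test_probe_order_by_suffix_then_lexicographic(tiny_store):
    store, _ = tiny_store
    assert store.probe_sets_for_ensembl("ENSG00000109320") == [
        "209239_at",
        "209240_x_at",
    ]
    assert [probe_suffix_rank(p) for p in ("x_at", "x_s_at", "x_x_at", "AFFX")] == [
        0, 1, 2, 3,
    ]


def test_zero_ncbi_rows_build_and_empty_queries():
    store = build_store(
        [AffyAnnotationRow(probe_set_id="1_at")], [], [], [], []
    )
    assert store.entrez_for_accession("NM_012242") == []
    assert store.probe_sets_for_ensembl("ENSG00000000000") == []


def test_accession_and_symbol_lookups(tiny_store):
    store, _ = tiny_store
    assert store.entrez_for_accession("NM_012242") == [22943]
    assert store.entrez_for_accession("NM_012242.4") == [22943]  # version tolerated
    assert store.probe_sets_for_symbol("dkk1") == store.probe_sets_for_symbol("DKK1")
    assert store.probe_sets_for_symbol("DKK1") == ["204602_at"]
    assert store.entrez_for_accession("XX_000000") == []


def test_synonyms_consulted_only_on_primary_miss(tiny_store):
    store, _ = tiny_store
    # "SK" is both a primary symbol (999001) and a DKK1 synonym: primary wins
    assert store.entrez_for_symbol("SK") == [999001]
    # "DKK-1" exists only as a synonym
    assert store.entrez_for_symbol("DKK-1") == [22943]


class TestGenesInLocus:
    def test_exact_span_and_boundary_touch(self, tiny_store):
        store, _ = tiny_store
        exact = store.genes_in_locus("chr4", 1795039, 1810599)
        assert [l.ensembl_gene_id for l in exact] == ["ENSG00000068078"]
        touch = store.genes_in_locus("chr4", 1810599, 1810599)  # gene's last base
        assert [l.ensembl_gene_id for l in touch] == ["ENSG00000068078"]

    def test_query_spanning_both_chr4p16_genes(self, tiny_store):
        store, _ = tiny_store
        both = store.genes_in_locus("chr4", 1_700_000, 2_000_000)
        assert [l.gene_name for l in both] == ["FGFR3", "WHSC1"]

    def test_invalid_interval(self, tiny_store):
        store, _ = tiny_store
        with pytest.raises(ValueError):
            store.genes_in_locus("chr4", 10, 5)

    def test_equals_brute_force_scan(self, tiny_store):
        store, loci = tiny_store
        queries = [
            ("chr4", 1, 3_000_000),
            ("chr4", 1_810_599, 1_873_151),
            ("chr10", 54_000_000, 54_074_056),
            ("chr10", 54_077_417, 60_000_000),
            ("chrX", 1, 10**9),
        ]
        for chrom, start, end in queries:
            brute = sorted(
                (
                    l
                    for l in loci
                    if l.chrom == chrom and l.start <= end and l.end >= start
                ),
                key=lambda l: (l.start, l.ensembl_gene_id),
            )
            assert store.genes_in_locus(chrom, start, end) == brute


def test_genes_for_cytoband(tiny_store):
    store, _ = tiny_store
    assert store.genes_for_cytoband("chr4p16.3") == [
        "ENSG00000068078",
        "ENSG00000109685",
    ]
    assert store.genes_for_cytoband("CHR4P16.3") == store.genes_for_cytoband("chr4p16.3")
    assert store.genes_for_cytoband("chr9z99") == []


def test_store_persists_and_reopens(tiny_store, tmp_path):
    from probelink.xref_store import XrefStore

    store, _ = tiny_store
    path = tmp_path / "xref.db"
    store.save(path)
    reopened = XrefStore.open(path)
    assert reopened.probe_sets_for_ensembl("ENSG00000107984") == ["204602_at"]
    assert reopened.table_counts() == store.table_counts()
    reopened.close()


def test_rebuild_is_idempotent(bundle):
    from probelink.fixtures import load_bundle_store

    a = load_bundle_store(bundle)
    b = load_bundle_store(bundle)
    assert a.table_counts() == b.table_counts()
    for gene in ("ENSG00000107984", "ENSG00000109320"):
        assert a.probe_sets_for_ensembl(gene) == b.probe_sets_for_ensembl(gene)
    a.close()
    b.close()


def test_query_probe_sets_within_ingested_universe(store, h929_annotated):
    universe = store.probe_set_universe()
    for ann in h929_annotated:
        assert set(ann.association.probe_set_ids) <= universe
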