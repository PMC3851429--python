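"""Parsers for the NetAffx, BioMart, GTF and NCBI dialects."""

import gzip
import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probelink import annotation_ingest as ai
from probelink.errors import ParseError, SchemaError

NETAFFX = """\
#%netaffx-annotation-netaffx-build=33
"Probe Set ID","Gene Symbol","Representative Public ID","RefSeq Transcript ID","Entrez Gene","Ensembl","Chromosomal Location"
"204602_at","DKK1","NM_012242","NM_012242 /// BC108917.1","22943","ENSG00000107984","chr10q21.1"
"204380_s_at","FGFR3","NM_000142","---","2261","ENSG00000068078","chr4p16.3"
"999_at","---","---","---","---","---","---"
"""


def affy_rows():
    return ai.parse_affy_annotation(io.StringIO(NETAFFX))


class TestAffyAnnotation:
    def test_multi_value_cells_split_and_version_stripped(self):
        dkk1 = affy_rows()[0]
        assert dkk1.probe_set_id == "204602_at"
        assert dkk1.ensembl_gene_ids == ("ENSG00000107984",)
        assert dkk1.entrez_gene_ids == (22943,)
        # " /// " split then version strip, deduplicated
        assert dkk1.genbank_accessions == ("NM_012242", "BC108917")

    def test_missing_token_yields_empty_lists(self):
        empty = affy_rows()[2]
        assert empty.gene_symbols == ()
        assert empty.genbank_accessions == ()
        assert empty.entrez_gene_ids == ()
        assert empty.ensembl_gene_ids == ()
        assert empty.cytoband is None

    def test_missing_probe_set_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            ai.parse_affy_annotation(io.StringIO('"Gene Symbol"\n"DKK1"\n'))

    def test_ragged_line_reports_line_number(self):
        bad = NETAFFX + '"only_one_field"\n'
        with pytest.raises(ParseError, match="line 6"):
            ai.parse_affy_annotation(io.StringIO(bad))

    def test_parser_is_pure(self):
        assert affy_rows() == affy_rows()

    def test_no_field_equals_missing_token(self):
        for row in affy_rows():
            for values in (row.gene_symbols, row.genbank_accessions,
                           row.ensembl_gene_ids):
                assert ai.AFFY_MISSING not in values


class TestVersionStrip:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("NM_012242.4", "NM_012242"),
            ("BC108917.1", "BC108917"),
            ("NM_000142", "NM_000142"),
            ("FOO.bar", "FOO.bar"),  # non-numeric suffix untouched
        ],
    )
    def test_examples(self, raw, expected):
        assert ai.strip_accession_version(raw) == expected

    @settings(max_examples=50, derandomize=True)
    @given(
        stem=st.from_regex(r"[A-Z]{2}_\d{6}", fullmatch=True),
        version=st.integers(min_value=0, max_value=99),
    )
    def test_round_trip_property(self, stem, version):
        assert ai.strip_accession_version(f"{stem}.{version}") == stem
        assert ai.strip_accession_version(stem) == stem


class TestBioMart:
    def test_pairs_deduplicated_and_empty_probe_dropped(self):
        src = io.StringIO(
            "Ensembl Gene ID\tAffy HG U133-PLUS-2 probe set\n"
            "ENSG00000068078\t204380_s_at\n"
            "ENSG00000068078\t204380_s_at\n"
            "ENSG00000107984\t\n"
        )
        pairs = ai.parse_biomart_export(src)
        assert pairs == [ai.BioMartPair("ENSG00000068078", "204380_s_at")]

    def test_single_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            ai.parse_biomart_export(io.StringIO("ENSG00000068078\nENSG00000107984\n"))


GTF = """\
#!genome-build test
chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1"; gene_name "ALPHA";
chr1\tsrc\texon\t400\t500\t.\t+\t.\tgene_id "G1";
chr2\tsrc\texon\t7\t7\t.\t-\t.\tgene_id "G2";
chr3\tsrc\texon\t10\t20\t.\t+\t.\tgene_id "G3";
chr3\tsrc\texon\t30\t40\t.\t-\t.\tgene_id "G3";
"""


class TestGtf:
    def test_envelope_is_min_max_over_features(self):
        loci = {l.ensembl_gene_id: l for l in ai.parse_ensembl_gtf(io.StringIO(GTF))}
        assert (loci["G1"].start, loci["G1"].end) == (100, 500)
        assert loci["G1"].gene_name == "ALPHA"

    def test_degenerate_single_base_span(self):
        loci = {l.ensembl_gene_id: l for l in ai.parse_ensembl_gtf(io.StringIO(GTF))}
        assert (loci["G2"].start, loci["G2"].end) == (7, 7)

    def test_mixed_strand_gene_keeps_first_strand_and_warns(self, caplog):
        with caplog.at_level("WARNING"):
            loci = {l.ensembl_gene_id: l for l in ai.parse_ensembl_gtf(io.StringIO(GTF))}
        assert loci["G3"].strand == "+"
        assert (loci["G3"].start, loci["G3"].end) == (10, 40)
        assert any("both strands" in r.message for r in caplog.records)

    def test_envelope_property_covers_every_feature(self):
        # brute-force oracle: re-scan raw features against the envelopes
        loci = {l.ensembl_gene_id: l for l in ai.parse_ensembl_gtf(io.StringIO(GTF))}
        for line in GTF.splitlines():
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            gid = ai.parse_gtf_attributes(fields[8])["gene_id"]
            assert loci[gid].start <= int(fields[3])
            assert loci[gid].end >= int(fields[4])

    def test_short_line_and_missing_gene_id_are_parse_errors(self):
        with pytest.raises(ParseError):
            ai.parse_ensembl_gtf(io.StringIO("chr1\tsrc\texon\t1\t2\n"))
        with pytest.raises(ParseError):
            ai.parse_ensembl_gtf(
                io.StringIO('chr1\tsrc\texon\t1\t2\t.\t+\t.\tother "x";\n')
            )


G2A = (
    "#tax_id\tGeneID\tstatus\tRNA_nucleotide_accession.version\tgi\tprot\n"
    "9606\t22943\tVALIDATED\tNM_012242.4\t-\t-\n"
    "10090\t13380\tVALIDATED\tNM_010051.3\t-\t-\n"
    "9606\t22943\tVALIDATED\t-\t-\t-\n"
)


class TestNcbi:
    def test_gene2accession_version_strip_and_filters(self):
        links = ai.parse_gene2accession(io.StringIO(G2A), tax_filter=9606)
        assert links == [ai.NcbiAccessionLink(22943, "NM_012242", 9606)]

    def test_gene2accession_non_integer_gene_id(self):
        with pytest.raises(ParseError):
            ai.parse_gene2accession(
                io.StringIO("9606\tabc\tX\tNM_1.1\t-\t-\n"), tax_filter=9606
            )

    def test_gene_info_synonyms_split_and_missing(self):
        src = io.StringIO(
            "#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\n"
            "9606\t22943\tDKK1\t-\tSK|DKK-1\n"
            "9606\t595\tCCND1\t-\t-\n"
            "10090\t13380\tDkk1\t-\t-\n"
        )
        infos = ai.parse_gene_info(src, tax_filter=9606)
        assert infos == [
            ai.NcbiGeneInfo(22943, "DKK1", ("SK", "DKK-1")),
            ai.NcbiGeneInfo(595, "CCND1", ()),
        ]


def test_gzip_inputs_transparently_decompressed(tmp_path):
    path = tmp_path / "gene2accession.fixture.tsv.gz"
    with gzip.open(path, "wt") as fh:
        fh.write(G2A)
    assert ai.parse_gene2accession(path, tax_filter=9606) == [
        ai.NcbiAccessionLink(22943, "NM_012242", 9606)
    ]
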