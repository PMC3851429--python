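"""Deterministic miniature annotation + expression bundles.

Real analyses consume multi-hundred-megabyte annotation exports
(NetAffx CSV, BioMart TSV, Ensembl GTF, NCBI gene2accession and
gene_info). This module writes miniature but dialect-faithful
versions of all five, together with expression tables for the two
multiple-myeloma cell lines studied (H929 and RPMI-8226) whose rows
reproduce the published filtered results verbatim, matching
microarray intensity tables, and gene-set member lists.

The bundle also plants designed coverage of the whole identifier-
resolution cascade: genes resolvable only via accession-to-Entrez,
accession-to-Ensembl, symbol-to-Ensembl and symbol-to-Entrez routes,
plus genuinely unmappable records. Decoy genes are drawn from
reserved fake ID ranges (ENSG00000800xxx/9xxxxx, 8xxxxx/9xxxxx Entrez,
9xxxxx_at probe sets) so fixture identifiers can never be mistaken
for real annotation. Regeneration with the same seed is byte-
identical; a manifest records the seed and per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

# -- published filtered experimental results (verbatim strings) -------
# Columns: symbol, Ensembl gene, transcript, transcript FPKM,
#          gene FPKM, representative probe set, cytoband, intensity
H929_TABLE = (
    ("CCND1", "ENSG00000110092", "ENST00000539241", "19.5901", "42.7301", "208712_at", "chr11q13.2", "279.6"),
    ("CCND1", "ENSG00000110092", "CUFF.2094.1", "15.7855", "42.7301", "208712_at", "chr11q13.2", "279.6"),
    ("CCND1", "ENSG00000110092", "ENST00000227507", "7.35445", "42.7301", "208712_at", "chr11q13.2", "279.6"),
    ("CCND3", "ENSG00000112576", "ENST00000372991", "43.8105", "43.8105", "1562028_at", "chr6p21.1", "228.4"),
    ("DKK1", "ENSG00000107984", "ENST00000373970", "0.765215", "1.24334", "204602_at", "chr10q21.1", "521.7"),
    ("DKK1", "ENSG00000107984", "CUFF.403.1", "0.478122", "1.24334", "204602_at", "chr10q21.1", "521.7"),
    ("FGFR3", "ENSG00000068078", "ENST00000260795", "25.4733", "48.3278", "204380_s_at", "chr4p16.3", "870.7"),
    ("FGFR3", "ENSG00000068078", "CUFF.20476.3", "12.4934", "48.3278", "204380_s_at", "chr4p16.3", "870.7"),
    ("FGFR3", "ENSG00000068078", "CUFF.20476.2", "10.3612", "48.3278", "204380_s_at", "chr4p16.3", "870.7"),
    ("MAF", "ENSG00000178573", "ENST00000393350", "11.1179", "23.4381", "1566323_at", "chr16q23.1", "7.1"),
    ("MAF", "ENSG00000178573", "CUFF.7714.4", "7.70292", "23.4381", "1566323_at", "chr16q23.1", "7.1"),
    ("MAF", "ENSG00000178573", "ENST00000326043", "4.61729", "23.4381", "1566323_at", "chr16q23.1", "7.1"),
    ("MAFB", "ENSG00000204103", "ENST00000373313", "0.713849", "0.713849", "218559_s_at", "chr20q12", "141.9"),
    ("NFKB1", "ENSG00000109320", "CUFF.21095.8", "7.80674", "10.7257", "209239_at", "chr4q24", "977.1"),
    ("NFKB1", "ENSG00000109320", "CUFF.21095.12", "2.919", "10.7257", "209239_at", "chr4q24", "977.1"),
    ("WHSC1", "ENSG00000109685", "ENST00000508355", "121.89", "249.395", "1557780_at", "chr4p16.3", "643.5"),
    ("WHSC1", "ENSG00000109685", "CUFF.20684.17", "68.9562", "249.395", "1557780_at", "chr4p16.3", "643.5"),
    ("WHSC1", "ENSG00000109685", "ENST00000382891", "58.5494", "249.395", "1557780_at", "chr4p16.3", "643.5"),
)

RPMI_TABLE = (
    ("CCND3", "ENSG00000112576", "ENST00000372991", "137.068", "137.068", "1562028_at", "chr6p21.1", "188.9"),
    ("FGFR3", "ENSG00000068078", "CUFF.23217.9", "1.27549", "2.96453", "204380_s_at", "chr4p16.3", "202.9"),
    ("FGFR3", "ENSG00000068078", "ENST00000340107", "1.24395", "2.96453", "204380_s_at", "chr4p16.3", "202.9"),
    ("FGFR3", "ENSG00000068078", "ENST00000260795", "0.445095", "2.96453", "204380_s_at", "chr4p16.3", "202.9"),
    ("MAF", "ENSG00000178573", "ENST00000393350", "0.00202724", "0.00202724", "1566323_at", "chr16q23.1", "19.9"),
    ("NFKB1", "ENSG00000109320", "ENST00000505458", "17.3606", "29.4494", "209239_at", "chr4q24", "1253.8"),
    ("NFKB1", "ENSG00000109320", "ENST00000226574", "12.0888", "29.4494", "209239_at", "chr4q24", "1253.8"),
    ("WHSC1", "ENSG00000109685", "ENST00000382891", "38.771", "55.1773", "1557780_at", "chr4p16.3", "32.2"),
)

# symbol -> (ensembl, entrez, probe set, cytoband, accession,
#            chrom, start, end, strand)  — hg19-approximate loci
MM_GENES = {
    "CCND1": ("ENSG00000110092", 595, "208712_at", "chr11q13.2", "NM_053056", "chr11", 69455873, 69469242, "+"),
    "CCND3": ("ENSG00000112576", 896, "1562028_at", "chr6p21.1", "NM_001760", "chr6", 41902671, 42018254, "-"),
    "DKK1": ("ENSG00000107984", 22943, "204602_at", "chr10q21.1", "NM_012242", "chr10", 54074056, 54077416, "+"),
    "FGFR3": ("ENSG00000068078", 2261, "204380_s_at", "chr4p16.3", "NM_000142", "chr4", 1795039, 1810599, "+"),
    "MAF": ("ENSG00000178573", 4094, "1566323_at", "chr16q23.1", "NM_005360", "chr16", 79627745, 79634622, "-"),
    "MAFB": ("ENSG00000204103", 9935, "218559_s_at", "chr20q12", "NM_005461", "chr20", 39314487, 39317880, "-"),
    "NFKB1": ("ENSG00000109320", 4790, "209239_at", "chr4q24", "NM_003998", "chr4", 103422486, 103538459, "+"),
    "WHSC1": ("ENSG00000109685", 7468, "1557780_at", "chr4p16.3", "NM_133330", "chr4", 1873151, 1983934, "+"),
}

MM_SYNONYMS = {"DKK1": ("SK", "DKK-1"), "WHSC1": ("NSD2", "MMSET"), "MAF": ("c-MAF",)}

# Cascade-coverage specials: each resolvable by exactly one branch.
ACC_ENTREZ_LABEL = "NM_800001"   # accession -> Entrez 800001 -> 800001_at
ACC_ENSEMBL_LABEL = "BC800002"   # accession -> ENSG00000800002 -> 800002_at
SYM_DIRECT_LABEL = "SYMD1"       # NetAffx symbol -> 800010_at
SYM_ENSEMBL_LABEL = "SYMENS"     # GTF gene_name -> ENSG00000800003 -> 800003_at
SYM_ENTREZ_LABEL = "SYMENT"      # gene_info symbol -> 800004 -> 800004_at
UNMAPPED_GENE_ID = "CUFF.999001"
UNMAPPED_LABEL = "ZZZNOTAGENE"

AFFY_HEADER = (
    "Probe Set ID", "Gene Symbol", "Representative Public ID",
    "RefSeq Transcript ID", "Entrez Gene", "Ensembl", "Chromosomal Location",
)

EXPRESSION_HEADER = "Gene ID\tGene Name\tTranscript ID\tFPKM\tGene FPKM"


@dataclass(frozen=True)
class FixtureBundle:
    root: Path
    affy_csv: Path
    biomart_tsv: Path
    ensembl_gtf: Path
    assembled_gtf_h929: Path
    assembled_gtf_rpmi: Path
    gene2accession_tsv: Path
    gene_info_tsv: Path
    h929_expression: Path
    rpmi_expression: Path
    gep_cohort_expression: Path
    h929_microarray: Path
    rpmi_microarray: Path
    gene_set_dir: Path
    manifest: Path


def _decoy_ensembl(i: int) -> str:
    return f"ENSG{900000 + i:011d}"


def _decoy_probe(i: int) -> str:
    return f"{900000 + i}_at"


def _decoy_entrez(i: int) -> int:
    return 900000 + i


def _decoy_symbol(i: int) -> str:
    return f"DEC{i:03d}"


def _decoy_accession(i: int) -> str:
    return f"NM_9{i:05d}"


def _csv_quote(fields) -> str:
    return ",".join('"' + f + '"' for f in fields)


def _gtf_line(chrom, source, feature, start, end, strand, attrs) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
    return f"{chrom}\t{source}\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attr_str}"


def _transcript_exons(start: int, end: int, k: int) -> list[tuple[int, int]]:
    """Two deterministic exons for transcript #k inside a gene span."""
    span = end - start
    off = (k * 137) % max(1, span // 4)
    exon1 = (start + off, start + off + max(1, span // 10))
    exon2 = (end - max(1, span // 12) - off, end - off)
    if exon2[0] <= exon1[1]:
        return [(start, end)]
    return [exon1, exon2]


def make_fixture_bundle(
    seed: int, out_dir: str | Path, n_decoy_genes: int = 90
) -> FixtureBundle:
    """Write a complete annotation + expression bundle under ``out_dir``.

    Decoy gene count must cover the packaged GEP-80 stand-in (80
    probe-set members, drawn from the first 80 decoys). All
    randomness (decoy loci, decoy expression, decoy intensities) comes
    from one ``random.Random(seed)``; everything else is fixed, so the
    published table rows are reproduced exactly regardless of seed.
    """
    if n_decoy_genes < 80:
        raise ValueError("need >=80 decoy genes to cover the GEP-80 stand-in")
    rng = random.Random(seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)

    # --- decoy gene plan (loci seeded, identifiers fixed) ------------
    decoys = []
    for i in range(1, n_decoy_genes + 1):
        chrom = f"chr{rng.randint(1, 22)}"
        start = rng.randint(100_000, 200_000_000)
        length = rng.randint(2_000, 120_000)
        cyto = f"{chrom}{rng.choice('pq')}{rng.randint(11, 36)}.{rng.randint(1, 3)}"
        decoys.append(
            {
                "i": i,
                "symbol": _decoy_symbol(i),
                "ensembl": _decoy_ensembl(i),
                "entrez": _decoy_entrez(i),
                "probe": _decoy_probe(i),
                "accession": _decoy_accession(i),
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": rng.choice("+-"),
                "cytoband": cyto,
            }
        )

    # --- NetAffx annotation CSV --------------------------------------
    affy_csv = root / "HG-U133_Plus_2.na33.annot.fixture.csv"
    lines = [
        "#%netaffx-annotation-netaffx-build=33",
        "#%netaffx-annotation-date=2012-10-30",
        "#%miniature synthetic fixture: identifiers in reserved fake ranges",
        _csv_quote(AFFY_HEADER),
    ]
    # MM genes: symbol+accession+entrez always; Ensembl cross reference
    # present for half the genes (the rest resolve via BioMart only).
    affy_has_ensembl = {"CCND1", "DKK1", "MAFB", "NFKB1"}
    for sym, (ensg, entrez, probe, cyto, acc, *_rest) in MM_GENES.items():
        lines.append(
            _csv_quote(
                (
                    probe,
                    sym,
                    acc,
                    f"{acc} /// {acc.replace('NM_', 'XM_')}.2",
                    str(entrez),
                    ensg if sym in affy_has_ensembl else "---",
                    cyto,
                )
            )
        )
    # cascade specials
    lines.append(_csv_quote(("800001_at", "---", "---", "---", "800001", "---", "---")))
    lines.append(_csv_quote(("800002_at", "---", ACC_ENSEMBL_LABEL, "---", "---", "ENSG00000800002", "---")))
    lines.append(_csv_quote(("800004_at", "---", "---", "---", "800004", "---", "---")))
    lines.append(_csv_quote(("800010_at", SYM_DIRECT_LABEL, "---", "---", "---", "---", "---")))
    for d in decoys:
        lines.append(
            _csv_quote(
                (
                    d["probe"],
                    d["symbol"],
                    d["accession"],
                    "---",
                    str(d["entrez"]),
                    d["ensembl"],
                    d["cytoband"],
                )
            )
        )
    affy_csv.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # --- BioMart export TSV ------------------------------------------
    biomart_tsv = root / "biomart_ensembl_affy.fixture.tsv"
    lines = ["Ensembl Gene ID\tAffy HG U133-PLUS-2 probe set"]
    for sym, (ensg, _e, probe, *_rest) in MM_GENES.items():
        lines.append(f"{ensg}\t{probe}")
    lines.append("ENSG00000800003\t800003_at")  # symbol->Ensembl special
    for d in decoys:
        lines.append(f"{d['ensembl']}\t{d['probe']}")
        lines.append(f"{d['ensembl']}\t")  # empty probe set rows occur in exports
    biomart_tsv.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # --- Ensembl reference GTF ---------------------------------------
    ensembl_gtf = root / "Homo_sapiens.GRCh37.fixture.gtf"
    known_transcripts: dict[str, list[str]] = {}
    for rows in (H929_TABLE, RPMI_TABLE):
        for sym, ensg, tid, *_ in rows:
            if tid.startswith("ENST"):
                known_transcripts.setdefault(sym, [])
                if tid not in known_transcripts[sym]:
                    known_transcripts[sym].append(tid)
    lines = ["#!genome-build GRCh37 (miniature synthetic fixture)"]
    for sym, (ensg, _e, _p, _c, _a, chrom, start, end, strand) in MM_GENES.items():
        lines.append(
            _gtf_line(chrom, "protein_coding", "gene", start, end, strand,
                      [("gene_id", ensg), ("gene_name", sym)])
        )
        for k, tid in enumerate(known_transcripts.get(sym, [])):
            for es, ee in _transcript_exons(start, end, k):
                lines.append(
                    _gtf_line(chrom, "protein_coding", "exon", es, ee, strand,
                              [("gene_id", ensg), ("transcript_id", tid),
                               ("gene_name", sym)])
                )
    lines.append(
        _gtf_line("chr15", "protein_coding", "gene", 5_000_000, 5_020_000, "+",
                  [("gene_id", "ENSG00000800003"), ("gene_name", SYM_ENSEMBL_LABEL)])
    )
    for d in decoys:
        attrs = [("gene_id", d["ensembl"]), ("gene_name", d["symbol"])]
        lines.append(
            _gtf_line(d["chrom"], "protein_coding", "gene", d["start"], d["end"],
                      d["strand"], attrs)
        )
        tid = f"ENST{900000 + d['i']:011d}"
        for es, ee in _transcript_exons(d["start"], d["end"], 0):
            lines.append(
                _gtf_line(d["chrom"], "protein_coding", "exon", es, ee, d["strand"],
                          attrs + [("transcript_id", tid)])
            )
    ensembl_gtf.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # --- assembled-transcript GTFs (Cufflinks-style, incl. CUFF.*) ----
    def write_assembled(path: Path, table) -> None:
        lines = []
        per_gene_idx: dict[str, int] = {}
        for sym, ensg, tid, fpkm, *_ in table:
            meta = MM_GENES[sym]
            chrom, gstart, gend, strand = meta[5], meta[6], meta[7], meta[8]
            k = per_gene_idx.get(sym, 0)
            per_gene_idx[sym] = k + 1
            for es, ee in _transcript_exons(gstart, gend, k):
                lines.append(
                    _gtf_line(chrom, "Cufflinks", "exon", es, ee, strand,
                              [("gene_id", ensg), ("transcript_id", tid),
                               ("FPKM", fpkm), ("gene_name", sym)])
                )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    assembled_h929 = root / "assembled_transcripts.h929.fixture.gtf"
    assembled_rpmi = root / "assembled_transcripts.rpmi8226.fixture.gtf"
    write_assembled(assembled_h929, H929_TABLE)
    write_assembled(assembled_rpmi, RPMI_TABLE)

    # --- NCBI gene2accession / gene_info ------------------------------
    gene2acc = root / "gene2accession.fixture.tsv"
    lines = [
        "#tax_id\tGeneID\tstatus\tRNA_nucleotide_accession.version"
        "\tRNA_nucleotide_gi\tprotein_accession.version"
    ]

    def acc_row(tax, geneid, acc):
        return f"{tax}\t{geneid}\tVALIDATED\t{acc}\t-\t-"

    for sym, (ensg, entrez, _p, _c, acc, *_rest) in MM_GENES.items():
        lines.append(acc_row(9606, entrez, f"{acc}.4"))
    lines.append(acc_row(9606, 800001, f"{ACC_ENTREZ_LABEL}.2"))
    lines.append(acc_row(10090, 13380, "NM_010051.3"))  # non-human, dropped
    lines.append(acc_row(9606, 800001, "-"))  # missing accession, dropped
    for d in decoys:
        lines.append(acc_row(9606, d["entrez"], f"{d['accession']}.1"))
    gene2acc.write_text("\n".join(lines) + "\n", encoding="utf-8")

    gene_info = root / "gene_info.fixture.tsv"
    lines = ["#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs"]

    def info_row(tax, geneid, sym, syns):
        return f"{tax}\t{geneid}\t{sym}\t-\t{syns}\t-"

    for sym, (ensg, entrez, *_rest) in MM_GENES.items():
        syns = "|".join(MM_SYNONYMS.get(sym, ())) or "-"
        lines.append(info_row(9606, entrez, sym, syns))
    lines.append(info_row(9606, 800001, "ACCENTG", "-"))
    lines.append(info_row(9606, 800004, SYM_ENTREZ_LABEL, "-"))
    lines.append(info_row(10090, 13380, "Dkk1", "-"))
    for d in decoys:
        lines.append(info_row(9606, d["entrez"], d["symbol"], f"ALT{d['i']:03d}"))
    gene_info.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # --- expression tables --------------------------------------------
    def special_rows() -> list[str]:
        return [
            f"-\t{SYM_DIRECT_LABEL}\t-\t-\t-",
            f"-\t{ACC_ENTREZ_LABEL}\t-\t-\t-",
            f"-\t{ACC_ENSEMBL_LABEL}\t-\t-\t-",
            f"-\t{SYM_ENSEMBL_LABEL}\t-\t-\t-",
            f"-\t{SYM_ENTREZ_LABEL}\t-\t-\t-",
            f"{UNMAPPED_GENE_ID}\t-\t{UNMAPPED_GENE_ID}.1\t0.5\t0.5",
            f"-\t{UNMAPPED_LABEL}\t-\t-\t-",
        ]

    def decoy_expr_rows(count: int) -> list[str]:
        rows = []
        for d in decoys[:count]:
            fpkm = f"{rng.uniform(0.05, 300):.5g}"
            tid = f"ENST{900000 + d['i']:011d}"
            rows.append(f"{d['ensembl']}\t{d['symbol']}\t{tid}\t{fpkm}\t{fpkm}")
        return rows

    h929_expr = root / "h929_expression.fixture.tsv"
    rows = [EXPRESSION_HEADER]
    rows += ["\t".join((g, s, t, f, gf)) for s, g, t, f, gf, *_ in H929_TABLE]
    rows += special_rows()
    rows += decoy_expr_rows(10)
    h929_expr.write_text("\n".join(rows) + "\n", encoding="utf-8")

    rpmi_expr = root / "rpmi8226_expression.fixture.tsv"
    rows = [EXPRESSION_HEADER]
    rows += ["\t".join((g, s, t, f, gf)) for s, g, t, f, gf, *_ in RPMI_TABLE]
    rows += special_rows()
    rows += decoy_expr_rows(10)
    rpmi_expr.write_text("\n".join(rows) + "\n", encoding="utf-8")

    # cohort table covering every decoy gene (GEP stand-in filtering)
    gep_cohort = root / "gep_cohort_expression.fixture.tsv"
    rows = [EXPRESSION_HEADER]
    rows += decoy_expr_rows(n_decoy_genes)
    gep_cohort.write_text("\n".join(rows) + "\n", encoding="utf-8")

    # --- microarray intensity tables ----------------------------------
    def write_microarray(path: Path, table) -> None:
        rows = ["probe_set_id\tintensity"]
        printed = {}
        for sym, _g, _t, _f, _gf, probe, _c, intensity in table:
            printed.setdefault(probe, intensity)
        for probe, intensity in printed.items():
            rows.append(f"{probe}\t{intensity}")
        for d in decoys:
            rows.append(f"{d['probe']}\t{rng.uniform(10, 2000):.1f}")
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")

    h929_micro = root / "h929_microarray.fixture.tsv"
    rpmi_micro = root / "rpmi8226_microarray.fixture.tsv"
    write_microarray(h929_micro, H929_TABLE)
    write_microarray(rpmi_micro, RPMI_TABLE)

    # --- gene-set member lists (copies of the packaged catalog) -------
    gene_set_dir = root / "gene_sets"
    gene_set_dir.mkdir(exist_ok=True)
    catalog = resources.files("probelink") / "catalog"
    for name in ("MM8.txt", "GEP-70.txt", "GEP-80.txt"):
        (gene_set_dir / name).write_text(
            (catalog / name).read_text(encoding="utf-8"), encoding="utf-8"
        )

    # --- manifest ------------------------------------------------------
    files = {
        "affy_csv": affy_csv,
        "biomart_tsv": biomart_tsv,
        "ensembl_gtf": ensembl_gtf,
        "assembled_gtf_h929": assembled_h929,
        "assembled_gtf_rpmi": assembled_rpmi,
        "gene2accession_tsv": gene2acc,
        "gene_info_tsv": gene_info,
        "h929_expression": h929_expr,
        "rpmi_expression": rpmi_expr,
        "gep_cohort_expression": gep_cohort,
        "h929_microarray": h929_micro,
        "rpmi_microarray": rpmi_micro,
    }
    manifest = root / "manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "seed": seed,
                "n_decoy_genes": n_decoy_genes,
                "sha256": {
                    key: hashlib.sha256(path.read_bytes()).hexdigest()
                    for key, path in sorted(files.items())
                },
            },
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )

    return FixtureBundle(
        root=root,
        assembled_gtf_h929=assembled_h929,
        assembled_gtf_rpmi=assembled_rpmi,
        gene_set_dir=gene_set_dir,
        manifest=manifest,
        **{k: v for k, v in files.items() if k not in (
            "assembled_gtf_h929", "assembled_gtf_rpmi")},
    )


def load_bundle_store(bundle: FixtureBundle, path: str | Path | None = None):
    """Ingest a bundle's five annotation files and build the store."""
    from . import annotation_ingest as ai
    from .xref_store import build_store

    return build_store(
        affy_rows=ai.parse_affy_annotation(bundle.affy_csv),
        biomart_pairs=ai.parse_biomart_export(bundle.biomart_tsv),
        ncbi_links=ai.parse_gene2accession(bundle.gene2accession_tsv),
        ncbi_info=ai.parse_gene_info(bundle.gene_info_tsv),
        gene_loci=ai.parse_ensembl_gtf(bundle.ensembl_gtf),
        path=path,
    )


def read_microarray_table(source) -> dict[str, float]:
    """Read a two-column probe-set/intensity TSV into a mapping."""
    from .annotation_ingest import _open_text

    handle, close = _open_text(source)
    try:
        out: dict[str, float] = {}
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            probe, value = line.split("\t")[:2]
            if lineno == 1 and not value.replace(".", "").isdigit():
                continue  # header
            out[probe] = float(value)
        return out
    finally:
        if close:
            handle.close()
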