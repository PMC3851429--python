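# probelink

Associate historical Affymetrix microarray probe sets with RNA-seq gene
and isoform expression.

## The problem

Many disease-focused groups — the motivating case here is multiple
myeloma (MM) — accumulated years of transcriptome data on Affymetrix
HG-U133 Plus 2 arrays before moving to RNA-seq. The array era produced
probe-set-level assets (prognostic signatures such as the 70-probe-set
GEP-70 risk score, molecular subtype classifiers, drug-target
discoveries like *DKK1*) that remain scientifically and clinically
valuable. RNA-seq output, however, speaks Ensembl gene and transcript
IDs and FPKM, not probe sets. `probelink` bridges the two worlds:

1. **Cross-reference store** — public annotation exports (the NetAffx
   annotation CSV, an Ensembl BioMart gene↔probe-set TSV, an Ensembl
   GTF, NCBI `gene2accession` and `gene_info`) are parsed into a set of
   indexed look-up tables inside an embedded sqlite database.
2. **Association cascade** — each RNA-seq record (Ensembl gene ID in
   column 1, gene symbol or GenBank accession in column 2, arbitrary
   extra columns carried verbatim) is resolved to probe set IDs by a
   *direct* method (Ensembl ID or symbol straight to probe set) and,
   when that fails, *indirect* methods in fixed order:
   accession → Entrez → probe set; accession → Ensembl gene → probe
   set; symbol → Ensembl gene → probe set; symbol → Entrez → probe
   set. Records that exhaust the cascade (e.g. novel `CUFF.*`
   Cufflinks genes) are reported unmapped. Locus-based association
   (chromosomal interval → overlapping genes → probe sets) is also
   provided.
3. **Gene-set filtering** — annotated tables are reduced to the
   members of a named set (probe sets, symbols or gene IDs); an
   8-gene MM list and stand-in GEP-70/GEP-80 catalogs ship with the
   package.
4. **Isoform trees** — transcript-level FPKM records are grouped per
   gene; the gene FPKM is the sum of isoform FPKMs, novel transcripts
   are flagged by their assembler prefix (`CUFF.`), dominant isoforms
   and novel-expression fractions are computed, and reported gene
   totals are cross-checked against the isoform sums.
5. **Visualization and IGV export** — a two-section figure juxtaposes
   log2(microarray intensity) and log2(FPKM) per gene and decomposes
   each gene into isoform bars (novel forms starred); a selected set
   of isoforms can be exported as a GTF plus an IGV batch script
   (`new` / `genome` / `load` / `goto` / `snapshot`).

## Worked example

Everything runs on a miniature, dialect-faithful annotation bundle
generated by `probelink.fixtures` (no downloads needed); the bundle
embeds the published filtered expression tables for the MM cell lines
H929 and RPMI-8226. From `examples/03_gene_set_filtering.py`:

```
H929: kept 18/35 records, 8 of 8 genes observed (0 members not observed)
RPMI-8226: kept 8/25 records, 5 of 8 genes observed (3 members not observed)
GEP-70 stand-in: 70 genes
```

All 18 H929 transcript rows of the eight key MM genes survive the MM8
filter; in RPMI-8226 only five of the eight genes produced
transcripts. From `examples/04_isoform_trees.py`, one isoform tree:

```
DKK1 (ENSG00000107984)  gene FPKM 1.24334
  ENST00000373970  0.765215
  CUFF.403.1  0.478122 *
  dominant: ENST00000373970  novel fraction: 0.385
```

The known isoform and a novel (`CUFF.`-prefixed, starred) isoform sum
to the gene FPKM; 38.5% of *DKK1* expression comes from the novel
form. The totals check also flags genuine inconsistencies — in
RPMI-8226 the listed WHSC1 isoform (38.771) does not account for the
reported gene FPKM (55.1773), indicating isoforms missing from the
input table.

The same pipeline is scriptable from the shell:

```sh
probelink make-fixtures --seed 1 --out-dir bundle
probelink build-store --affy bundle/HG-U133_Plus_2.na33.annot.fixture.csv \
    --biomart bundle/biomart_ensembl_affy.fixture.tsv \
    --gtf bundle/Homo_sapiens.GRCh37.fixture.gtf \
    --gene2accession bundle/gene2accession.fixture.tsv \
    --gene-info bundle/gene_info.fixture.tsv --out store.db
probelink annotate --store store.db --in bundle/h929_expression.fixture.tsv \
    --microarray bundle/h929_microarray.fixture.tsv --out annotated.tsv
probelink filter --in annotated.tsv --set MM8 --out filtered.tsv
probelink isoforms --in filtered.tsv --check-totals
```

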