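# Methods

## Cross-reference model

The package's core object is a set of relational look-up tables
linking five identifier namespaces: Affymetrix HG-U133 Plus 2 probe
set IDs, Ensembl gene IDs, Entrez gene IDs, GenBank RNA accessions,
and gene symbols, plus one chromosomal locus envelope per Ensembl
gene. Sources and the relations they feed:

| relation | sources |
|---|---|
| probe set ↔ Ensembl gene | NetAffx "Ensembl" column; BioMart export (union) |
| probe set ↔ Entrez gene | NetAffx "Entrez Gene" column |
| probe set ↔ symbol | NetAffx "Gene Symbol" column |
| probe set ↔ cytoband | NetAffx "Chromosomal Location" column |
| accession ↔ Entrez gene | NCBI `gene2accession` (tax 9606); NetAffx rows |
| accession ↔ Ensembl gene | NetAffx rows (accession and Ensembl ID co-listed) |
| symbol ↔ Ensembl gene | NetAffx rows; GTF `gene_name` |
| symbol ↔ Entrez gene | NCBI `gene_info` (primary + synonyms, flagged) |
| gene locus | GTF envelope: min start / max end over a gene's features |

Rows are deduplicated with merged provenance tags (`affy,biomart`
etc.), symbols are stored upper-cased, accessions version-stripped
(trailing `.N` removed only when `N` is all digits, so non-versioned
IDs are never mangled). The store is a single sqlite file (or
in-memory), read-only after build. Synonym matching is consulted only
when a primary-symbol lookup misses, to keep synonym collisions from
dominating results.

## Association cascade

Resolution is a fixed-order cascade that stops at the first branch
returning a non-empty probe set list: (1) direct by Ensembl gene ID
(Affy ∪ BioMart relations), else direct by label-as-symbol against
the NetAffx symbol column; (2) label-as-accession → Entrez → probe
sets, with the symbol back-filled from `gene_info`; (3) accession →
Ensembl gene → probe sets; (4) symbol → Ensembl gene → probe sets;
(5) symbol → Entrez → probe sets; otherwise unmapped. A label is
tried as an accession when it matches `^[A-Z]{1,3}_?\d+$` after
version-stripping; because short symbols like `DKK1` also match, the
symbol routes always run after a failed accession route. Probe sets
from different branches are never merged — the first winning branch
alone determines the result and its method attribution.

**Representative probe set.** Published result tables print one
probe set per gene, but no selection rule accompanies them; the rule
here is the package's own: with microarray intensities attached, the
most intense mapped probe set wins (ties by suffix rank, then name);
without intensities, probe sets rank by design suffix — unique `_at`
designs before cross-hybridizing `_s_at` before `_x_at` before
anything else — then lexicographically.

**Locus association.** Interval queries use closed-interval overlap
(≥1 shared base) on 1-based inclusive GTF coordinates; results are
ordered by start position then gene ID. The locus table stores one
envelope per gene (min/max over all its features); a gene whose
features disagree on strand keeps the first strand seen and logs a
warning.

## Expression I/O

The input contract is a tab-delimited table: column 1 Ensembl gene ID
(when known), column 2 symbol or accession, any further columns
carried verbatim. A header is auto-detected (first row whose column 1
is not ID-shaped) and can be forced off. Headers naming a
transcript/tracking ID or FPKM populate typed fields; FPKM values are
kept both parsed and as exact input strings, and output echoes the
strings so round trips never re-round. The Cufflinks
`*.fpkm_tracking` dialect has a dedicated adapter (gene-level files
yield records without transcript IDs; the `-` missing token maps to
empty).

## Isoform trees and aggregation

Gene-level FPKM is the plain sum of isoform FPKMs (`math.fsum`);
FPKM is length-normalized, so isoform contributions add, and the
published tables confirm plain summation to within ~4×10⁻⁶ relative.
A reported gene total can arrive either as gene-level rows lacking a
transcript ID or as an extra column whose header contains "gene" and
"FPKM" (how the published tables carry it, repeated per isoform row);
the consistency check flags genes where
`|reported − computed| / max(reported, tiny)` exceeds a tolerance
(default 1e-5). One published RPMI-8226 gene (WHSC1, reported 55.1773
vs a single listed isoform at 38.771) fails this check; the package
flags it rather than guessing which isoforms were omitted.

Novelty is the literal, case-sensitive transcript-ID prefix `CUFF.`
(the Cufflinks convention for assembled transcripts absent from the
reference); other assemblers' prefixes are configurable. The dominant
isoform is the FPKM maximum (ties: lexicographically smallest ID);
the novel fraction is novel FPKM over total, undefined at zero total.

## Visualization and IGV export

Plots are log2-scaled on both platforms, following the common
practice for expression comparisons; the bars visualize the tabular
data and are not a cross-platform statistic. Nonpositive values have
no log2 and are excluded rather than pseudocounted (a pseudocount
would silently change printed values); every exclusion is listed in a
sidecar text file next to the figure. The IGV export writes a
`selection.gtf` restricted to the selected transcript IDs plus a
batch script (`new`, `genome <id>`, `load`, then one
`goto chrom:start-end` / `snapshot <gene>.png` pair per gene over the
envelope of its selected transcripts). Defaults: genome `hg19` (the
build the studied alignments used), locus padding 1000 bp — enough
flank to see neighboring context without leaving the gene's scale.
IGV itself is not embedded; an optional socket sender can drive a
running instance.

## Fixture bundles

`probelink.fixtures.make_fixture_bundle(seed, out_dir, n_decoy_genes=90)`
writes miniature, dialect-faithful versions of all five annotation
inputs plus expression, microarray and gene-set files. What it
emulates:

* the published filtered expression tables of cell lines H929 (18
  transcript rows over 8 MM genes) and RPMI-8226 (8 rows over 5
  genes) verbatim, including the printed representative probe sets,
  cytobands and microarray intensities, with hg19-approximate loci
  for the 8 genes;
* decoy genes drawn from reserved fake ID ranges
  (`ENSG000009xxxxx`, `9xxxxx_at`, Entrez 9xxxxx) with seeded loci
  and expression, so filters have something to remove and the GEP
  stand-ins (first 70/80 decoys) are fully present;
* designed cascade coverage: one gene resolvable only via each
  indirect branch (fixed `8xxxxx`-range identifiers) and genuinely
  unmappable records, so every method value is exercised.

Sample sizes follow the study's own scale: the published tables are
reproduced row-for-row, and the decoy cohort (90 genes) is the
smallest round size covering the 80-member GEP-80 stand-in with
headroom. All randomness flows from one `random.Random(seed)`;
identifiers and the published rows are seed-independent, so
regeneration with the same seed is byte-identical (checksummed in a
manifest). The generator does **not** simulate read alignment, FPKM
estimation noise, cross-hybridization, or annotation-release drift —
passing tests demonstrate correct identifier plumbing and arithmetic
on faithful dialects, not robustness to noisy real-world annotation.

The packaged GEP-70/GEP-80 catalogs are synthetic stand-ins (their
true memberships are published separately); they are plain text
files users can replace, and their headers say so.

## Numerical and degenerate-input choices

* Gene totals use `math.fsum`; comparisons are relative with a
  `1e-300` floor against division by zero.
* Ties: representative selection (intensity → suffix rank → name),
  dominant isoform (FPKM → name), isoform ordering (FPKM descending →
  name) are all total orders, so outputs are deterministic.
* Empty query results are values, not errors; only structurally
  invalid inputs (start > end, empty member lists, duplicate
  gene/transcript rows, malformed files) raise.
* Unmapped associations are logged and flow through annotation and
  filtering; a record whose association failed can still match a gene
  set by symbol or gene ID.

## Known limitations

* One probe set per MM gene in the fixtures; many-to-many
  probe-set/gene webs are exercised only in unit tests.
* Symbol→Ensembl matching has no synonym table (synonyms exist only
  on the Entrez side, as NCBI ships them).
* No fuzzy symbol matching, genome-build liftover, or non-human taxa
  beyond the tax-ID filter; non-Affymetrix platforms are out of
  scope.
* The figure reproduces values and annotations, not the published
  figures' pixel layout.
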