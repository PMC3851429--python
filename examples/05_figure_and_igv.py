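"""Comparison figure and IGV batch export.

Renders the two-section comparison figure (log2 microarray intensity
vs log2 RNA-seq FPKM per gene; isoform composition with novel forms
starred) and exports an FGFR3 isoform selection as a GTF plus an IGV
batch script.
"""

import tempfile
from pathlib import Path

from probelink.expression_io import annotate_records, read_expression_table
from probelink.fixtures import (
    load_bundle_store,
    make_fixture_bundle,
    read_microarray_table,
)
from probelink.geneset_filter import filter_records, load_gene_set
from probelink.isoform_model import build_trees
from probelink.viz_igv import export_igv, render_comparison

with tempfile.TemporaryDirectory() as tmp:
    bundle = make_fixture_bundle(seed=1, out_dir=Path(tmp) / "bundle")
    store = load_bundle_store(bundle)

    annotated = filter_records(
        annotate_records(
            read_expression_table(bundle.h929_expression),
            store,
            read_microarray_table(bundle.h929_microarray),
        ),
        load_gene_set("MM8"),
    )
    trees = build_trees([a.record for a in annotated])
    intensities = {
        a.record.label: a.microarray_expression
        for a in annotated
        if a.microarray_expression is not None
    }
    fig, note = render_comparison(trees, intensities, Path(tmp) / "panel.png")
    print(f"figure: {fig}  (exclusion note: {note})")

    out = export_igv(
        [("FGFR3", ["ENST00000260795", "CUFF.20476.3", "CUFF.20476.2"])],
        bundle.assembled_gtf_h929,
        out_dir=Path(tmp) / "igv",
    )
    print(f"selection GTF: {out.gtf_path}")
    print("batch script:")
    print(out.batch_path.read_text())
    store.close()

# The batch script opens IGV on hg19, loads the selected isoforms and
# snapshots the padded FGFR3 locus, so novel and annotated isoforms
# can be compared visually.
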