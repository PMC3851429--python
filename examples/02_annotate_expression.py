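"""Annotate an RNA-seq expression table with probe-set associations.

Reads the H929-like expression table (Ensembl gene ID in column 1,
symbol in column 2, transcript/FPKM columns carried through), resolves
every record, attaches microarray intensities via each gene's
representative probe set, and writes the annotated TSV.
"""

import tempfile
from pathlib import Path

from probelink.expression_io import (
    annotate_records,
    read_expression_table,
    write_annotated_table,
)
from probelink.fixtures import (
    load_bundle_store,
    make_fixture_bundle,
    read_microarray_table,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = make_fixture_bundle(seed=1, out_dir=Path(tmp) / "bundle")
    store = load_bundle_store(bundle)

    records = read_expression_table(bundle.h929_expression)
    microarray = read_microarray_table(bundle.h929_microarray)
    annotated = annotate_records(records, store, microarray)

    out = Path(tmp) / "h929_annotated.tsv"
    write_annotated_table(annotated, out)

    unmapped = sum(1 for a in annotated if not a.association.probe_set_ids)
    print(f"annotated {len(annotated)} records ({unmapped} unmapped)")
    for a in annotated[:5]:
        print(
            f"{a.record.label:8s} {a.association.representative_probe_set_id or '-':12s}"
            f" {a.cytoband or '-':12s} intensity={a.microarray_expression}"
        )
    store.close()

# The intensity column carries the microarray signal of each gene's
# representative probe set, juxtaposing the historical array
# measurement with the RNA-seq FPKM in one table.
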