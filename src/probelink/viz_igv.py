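"""Comparison graphics and IGV export.

Two read-outs of the same genes — normalized microarray intensity and
RNA-seq FPKM — are juxtaposed on a log2 scale: section A shows one
grouped bar pair per gene, section B decomposes each gene's RNA-seq
total into its isoforms, marking novel (assembler-discovered)
transcripts with an asterisk. The bars visualize the tabular data;
the two platforms' units are not directly comparable, so no cross-
platform statistic is drawn from them. Nonpositive values have no
log2 and are excluded from the plot; exclusions are listed in a
sidecar note rather than silently dropped.

For locus-level inspection, a selection of isoforms can be exported as
a transcript GTF plus an IGV batch script (new / genome / load / goto
/ snapshot), so the Integrative Genomics Viewer can be driven over the
selected genes without manual navigation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .annotation_ingest import _open_text, parse_gtf_attributes
from .errors import ExportError, ProbelinkError
from .isoform_model import IsoformTree, log2_expression


@dataclass(frozen=True)
class GeneBars:
    """Section-A entry: one gene's two log2 bars (None = excluded)."""

    label: str
    log2_microarray: float | None
    log2_rnaseq: float | None


@dataclass(frozen=True)
class IsoformBar:
    """Section-B entry: one isoform's log2 bar with novelty marker."""

    gene_label: str
    transcript_id: str
    log2_fpkm: float | None
    novel: bool


@dataclass(frozen=True)
class ComparisonPanel:
    gene_bars: tuple[GeneBars, ...]
    isoform_bars: tuple[IsoformBar, ...]
    exclusions: tuple[str, ...]


def compute_panel(
    trees: Sequence[IsoformTree],
    microarray_by_gene: Mapping[str, float] | None = None,
) -> ComparisonPanel:
    """Compute the plot-ready panel values from isoform trees.

    Genes keep their input order. Microarray intensities are looked up
    by gene label, then gene ID. Every excluded (nonpositive or
    absent) value contributes one line to the exclusion note.
    """
    if not trees:
        raise ProbelinkError("no genes to plot")
    micro = microarray_by_gene or {}
    gene_bars: list[GeneBars] = []
    iso_bars: list[IsoformBar] = []
    notes: list[str] = []
    for tree in trees:
        intensity = micro.get(tree.gene_label, micro.get(tree.gene_id))
        lm = log2_expression(intensity) if intensity is not None else None
        if intensity is not None and lm is None:
            notes.append(f"{tree.gene_label}: nonpositive microarray intensity")
        elif intensity is None and microarray_by_gene is not None:
            notes.append(f"{tree.gene_label}: no microarray intensity")
        lr = log2_expression(tree.gene_fpkm_computed)
        if lr is None:
            notes.append(f"{tree.gene_label}: nonpositive gene FPKM")
        gene_bars.append(
            GeneBars(label=tree.gene_label, log2_microarray=lm, log2_rnaseq=lr)
        )
        for iso in tree.isoforms:
            lf = log2_expression(iso.fpkm)
            if lf is None:
                notes.append(
                    f"{tree.gene_label}/{iso.transcript_id}: nonpositive FPKM"
                )
            iso_bars.append(
                IsoformBar(
                    gene_label=tree.gene_label,
                    transcript_id=iso.transcript_id,
                    log2_fpkm=lf,
                    novel=iso.is_novel,
                )
            )
    return ComparisonPanel(
        gene_bars=tuple(gene_bars),
        isoform_bars=tuple(iso_bars),
        exclusions=tuple(notes),
    )


def render_comparison(
    trees: Sequence[IsoformTree],
    microarray_by_gene: Mapping[str, float] | None,
    sink: str | Path,
    dpi: int = 150,
) -> tuple[Path, Path]:
    """Render the two-section comparison figure.

    Writes the figure to ``sink`` (format from the extension) and an
    ``<stem>.exclusions.txt`` sidecar listing any values left out of
    the log2 plot. Returns both paths. Output is deterministic for
    fixed inputs.
    """
    panel = compute_panel(trees, microarray_by_gene)
    sink = Path(sink)

    fig, (ax_a, ax_b) = plt.subplots(
        2, 1, figsize=(max(6.0, 1.2 * len(panel.gene_bars)), 7.0)
    )

    xs = range(len(panel.gene_bars))
    width = 0.38
    ax_a.bar(
        [x - width / 2 for x in xs],
        [b.log2_microarray if b.log2_microarray is not None else 0 for b in panel.gene_bars],
        width,
        label="microarray",
        color="#4c72b0",
    )
    ax_a.bar(
        [x + width / 2 for x in xs],
        [b.log2_rnaseq if b.log2_rnaseq is not None else 0 for b in panel.gene_bars],
        width,
        label="RNA-seq",
        color="#dd8452",
    )
    ax_a.set_xticks(list(xs))
    ax_a.set_xticklabels([b.label for b in panel.gene_bars], rotation=45, ha="right")
    ax_a.set_ylabel("log2(expression)")
    ax_a.set_title("A. Gene expression: microarray vs RNA-seq")
    ax_a.legend()

    shown = [b for b in panel.isoform_bars if b.log2_fpkm is not None]
    xs_b = range(len(shown))
    ax_b.bar(list(xs_b), [b.log2_fpkm for b in shown], color="#55a868")
    labels = [
        f"{b.gene_label}\n{b.transcript_id}" + (" *" if b.novel else "")
        for b in shown
    ]
    ax_b.set_xticks(list(xs_b))
    ax_b.set_xticklabels(labels, rotation=60, ha="right", fontsize=6)
    ax_b.set_ylabel("log2(FPKM)")
    ax_b.set_title("B. Isoform composition (* = novel isoform)")

    fig.tight_layout()
    fig.savefig(sink, dpi=dpi)
    plt.close(fig)

    note_path = sink.with_suffix(".exclusions.txt")
    note_path.write_text(
        "\n".join(panel.exclusions) + ("\n" if panel.exclusions else ""),
        encoding="utf-8",
    )
    return sink, note_path


@dataclass(frozen=True)
class IgvExportBundle:
    gtf_path: Path
    batch_path: Path
    loci: tuple[tuple[str, str, int, int], ...]  # (gene_label, chrom, start, end)
    padding: int


def _transcript_features(gtf_source, wanted: set[str]) -> dict[str, list[str]]:
    """Collect raw GTF lines per wanted transcript_id."""
    handle, close = _open_text(gtf_source)
    try:
        found: dict[str, list[str]] = {t: [] for t in wanted}
        for line in handle:
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 9:
                continue
            tid = parse_gtf_attributes(fields[8]).get("transcript_id")
            if tid in found:
                found[tid].append(stripped)
        return found
    finally:
        if close:
            handle.close()


def export_igv(
    selection: Sequence[tuple[str, Sequence[str]]],
    gtf_source,
    out_dir: str | Path,
    genome_id: str = "hg19",
    padding: int = 1000,
) -> IgvExportBundle:
    """Write ``selection.gtf`` and ``igv_batch.txt`` for a selection.

    ``selection`` is a list of (gene label, transcript IDs). Features
    for every selected transcript are pulled from ``gtf_source`` (a
    reference GTF, or an assembled-transcript GTF for novel isoforms).
    The batch script opens a fresh IGV session on ``genome_id``, loads
    the exported GTF, and takes one goto+snapshot per gene over the
    envelope of its selected transcripts padded by ``padding`` bases.
    """
    if not selection:
        raise ExportError("empty selection: nothing to export")
    wanted: set[str] = set()
    for _, transcripts in selection:
        wanted.update(transcripts)
    if not wanted:
        raise ExportError("selection names no transcripts")
    features = _transcript_features(gtf_source, wanted)
    missing = sorted(t for t, lines in features.items() if not lines)
    if missing:
        raise ExportError(
            "no features found for transcript(s): " + ", ".join(missing)
        )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gtf_path = out_dir / "selection.gtf"
    with open(gtf_path, "wt", encoding="utf-8") as fh:
        for _, transcripts in selection:
            for tid in transcripts:
                for line in features[tid]:
                    fh.write(line + "\n")

    loci: list[tuple[str, str, int, int]] = []
    batch = ["new", f"genome {genome_id}", f"load {gtf_path.name}"]
    for gene_label, transcripts in selection:
        chroms: set[str] = set()
        start = None
        end = None
        for tid in transcripts:
            for line in features[tid]:
                fields = line.split("\t")
                chroms.add(fields[0])
                s, e = int(fields[3]), int(fields[4])
                start = s if start is None else min(start, s)
                end = e if end is None else max(end, e)
        if len(chroms) != 1:
            raise ExportError(
                f"gene {gene_label!r}: selected transcripts span chromosomes "
                f"{sorted(chroms)}"
            )
        chrom = chroms.pop()
        start = max(1, start - padding)
        end = end + padding
        loci.append((gene_label, chrom, start, end))
        batch.append(f"goto {chrom}:{start}-{end}")
        batch.append(f"snapshot {gene_label}.png")

    batch_path = out_dir / "igv_batch.txt"
    batch_path.write_text("\n".join(batch) + "\n", encoding="utf-8")
    return IgvExportBundle(
        gtf_path=gtf_path,
        batch_path=batch_path,
        loci=tuple(loci),
        padding=padding,
    )


def send_igv_batch(bundle: IgvExportBundle, host: str = "127.0.0.1", port: int = 60151) -> None:
    """Send the batch commands to a running IGV over its socket protocol."""
    import socket

    with socket.create_connection((host, port), timeout=10) as sock:
        for line in bundle.batch_path.read_text(encoding="utf-8").splitlines():
            sock.sendall((line + "\n").encode())
            sock.recv(4096)
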