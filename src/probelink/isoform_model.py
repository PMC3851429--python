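"""Per-gene isoform trees: aggregation, novelty, dominant forms.

RNA-seq quantifies expression at isoform resolution; grouping the
transcript-level FPKM records of one gene under a common root (the
"isoform tree") recovers the gene-level view microarrays provide,
while retaining the isoform decomposition. Transcripts assembled de
novo by Cufflinks carry a ``CUFF.`` prefix and are flagged as novel.

Gene-level FPKM is aggregated by plain summation of isoform FPKMs —
FPKM is a length-normalized rate, so isoform contributions add — and
an optional consistency check compares the sum against a reported
gene-level value when one is supplied (either as gene-level rows
without a transcript ID, or as a gene-FPKM column repeated on each
isoform row).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ProbelinkError
from .expression_io import ExpressionRecord

NOVEL_PREFIX = "CUFF."


@dataclass(frozen=True)
class Isoform:
    transcript_id: str
    fpkm: float
    is_novel: bool


@dataclass(frozen=True)
class IsoformTree:
    """One gene's transcripts, FPKM-descending, with the gene total."""

    gene_id: str
    gene_label: str
    isoforms: tuple[Isoform, ...]
    gene_fpkm_reported: float | None
    gene_fpkm_computed: float


@dataclass(frozen=True)
class TotalDiscrepancy:
    gene_id: str
    reported: float
    computed: float


def is_novel_transcript(transcript_id: str, novel_prefix: str = NOVEL_PREFIX) -> bool:
    """Literal, case-sensitive assembler-prefix test (default ``CUFF.``)."""
    return transcript_id.startswith(novel_prefix)


def build_trees(
    records: Sequence[ExpressionRecord],
    novel_prefix: str = NOVEL_PREFIX,
) -> list[IsoformTree]:
    """Group transcript records into one tree per distinct gene ID.

    Records lacking a transcript ID do not become tree members but may
    supply the gene's reported FPKM; so may an extra column whose
    header contains "gene" and "FPKM" (the first parseable value per
    gene wins). Trees come back in first-seen gene order; isoforms are
    sorted FPKM-descending with ties broken by transcript ID. A
    duplicate (gene, transcript) pair is a validation error.
    """
    members: dict[str, list[Isoform]] = {}
    labels: dict[str, str] = {}
    reported: dict[str, float] = {}
    seen_pairs: set[tuple[str, str]] = set()

    for record in records:
        gene = record.gene_id or record.label.upper()
        if not gene:
            continue
        labels.setdefault(gene, record.label or record.gene_id)
        if gene not in reported:
            for name, value in record.extra:
                low = name.lower()
                if "gene" in low and "fpkm" in low:
                    try:
                        reported[gene] = float(value)
                    except ValueError:
                        pass
                    break
        if record.transcript_id is None:
            if record.fpkm is not None:
                reported.setdefault(gene, record.fpkm)
            continue
        pair = (gene, record.transcript_id)
        if pair in seen_pairs:
            raise ProbelinkError(
                f"duplicate transcript row for gene {gene!r}, "
                f"transcript {record.transcript_id!r}"
            )
        seen_pairs.add(pair)
        members.setdefault(gene, []).append(
            Isoform(
                transcript_id=record.transcript_id,
                fpkm=record.fpkm if record.fpkm is not None else 0.0,
                is_novel=is_novel_transcript(record.transcript_id, novel_prefix),
            )
        )

    trees: list[IsoformTree] = []
    for gene, isoforms in members.items():
        ordered = tuple(sorted(isoforms, key=lambda i: (-i.fpkm, i.transcript_id)))
        trees.append(
            IsoformTree(
                gene_id=gene,
                gene_label=labels.get(gene, gene),
                isoforms=ordered,
                gene_fpkm_reported=reported.get(gene),
                gene_fpkm_computed=math.fsum(i.fpkm for i in ordered),
            )
        )
    return trees


def check_gene_totals(
    trees: Sequence[IsoformTree], relative_tolerance: float = 1e-5
) -> list[TotalDiscrepancy]:
    """Flag genes whose isoform sum disagrees with the reported total.

    A gene is flagged iff ``|reported - computed| / max(reported, tiny)``
    exceeds the tolerance; genes without a reported total are never
    flagged. Disagreement usually means the input table listed only a
    subset of the gene's isoforms.
    """
    if relative_tolerance <= 0:
        raise ValueError("relative_tolerance must be positive")
    tiny = 1e-300
    out = []
    for tree in trees:
        if tree.gene_fpkm_reported is None:
            continue
        err = abs(tree.gene_fpkm_reported - tree.gene_fpkm_computed)
        if err / max(tree.gene_fpkm_reported, tiny) > relative_tolerance:
            out.append(
                TotalDiscrepancy(
                    gene_id=tree.gene_id,
                    reported=tree.gene_fpkm_reported,
                    computed=tree.gene_fpkm_computed,
                )
            )
    return out


def dominant_isoform(tree: IsoformTree) -> str:
    """The transcript with maximal FPKM (ties: lexicographic smallest)."""
    if not tree.isoforms:
        raise ValueError(f"gene {tree.gene_id!r} has no isoforms")
    best = max(tree.isoforms, key=lambda i: (i.fpkm, ), default=None)
    top = min(
        (i for i in tree.isoforms if i.fpkm == best.fpkm),
        key=lambda i: i.transcript_id,
    )
    return top.transcript_id


def novel_fraction(tree: IsoformTree) -> float | None:
    """Share of the gene total carried by novel (assembled) isoforms.

    Undefined (None) when the gene total is zero.
    """
    if tree.gene_fpkm_computed <= 0:
        return None
    novel = math.fsum(i.fpkm for i in tree.isoforms if i.is_novel)
    return novel / tree.gene_fpkm_computed


def log2_expression(value: float) -> float | None:
    """log2 of a positive expression value; None signals plot exclusion."""
    if value <= 0:
        return None
    return math.log2(value)


def tree_as_text(tree: IsoformTree) -> str:
    """Indented text rendering of one gene's isoform tree."""
    lines = [
        f"{tree.gene_label} ({tree.gene_id})  "
        f"gene FPKM {tree.gene_fpkm_computed:g}"
    ]
    for iso in tree.isoforms:
        star = " *" if iso.is_novel else ""
        lines.append(f"  {iso.transcript_id}  {iso.fpkm:g}{star}")
    return "\n".join(lines)
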