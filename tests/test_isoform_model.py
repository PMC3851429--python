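"""Isoform trees: aggregation, totals check, dominance, novelty."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probelink.errors import ProbelinkError
from probelink.expression_io import ExpressionRecord
from probelink.isoform_model import (
    build_trees,
    check_gene_totals,
    dominant_isoform,
    is_novel_transcript,
    log2_expression,
    novel_fraction,
    tree_as_text,
)


def _rec(gene, label, transcript=None, fpkm=None, gene_fpkm=None):
    extra = (("Gene FPKM", str(gene_fpkm)),) if gene_fpkm is not None else ()
    return ExpressionRecord(
        gene_id=gene,
        label=label,
        transcript_id=transcript,
        fpkm=fpkm,
        fpkm_raw=None if fpkm is None else str(fpkm),
        extra=extra,
    )


CCND1 = [
    _rec("ENSG00000110092", "CCND1", "ENST00000539241", 19.5901, "42.7301"),
    _rec("ENSG00000110092", "CCND1", "CUFF.2094.1", 15.7855, "42.7301"),
    _rec("ENSG00000110092", "CCND1", "ENST00000227507", 7.35445, "42.7301"),
]


class TestBuildTrees:
    def test_three_isoform_gene_sums_and_sorts(self):
        (tree,) = build_trees(CCND1)
        assert len(tree.isoforms) == 3
        # hand sum of the three transcript FPKMs
        assert tree.gene_fpkm_computed == pytest.approx(42.73005, rel=1e-9)
        assert [i.fpkm for i in tree.isoforms] == sorted(
            (i.fpkm for i in tree.isoforms), reverse=True
        )
        assert tree.gene_fpkm_reported == pytest.approx(42.7301)

    def test_single_isoform_gene(self):
        (tree,) = build_trees(
            [_rec("ENSG00000112576", "CCND3", "ENST00000372991", 43.8105, "43.8105")]
        )
        assert tree.gene_fpkm_computed == pytest.approx(43.8105)

    def test_empty_input(self):
        assert build_trees([]) == []

    def test_gene_level_record_supplies_reported_total(self):
        trees = build_trees(
            [
                _rec("G1", "SYM", None, 10.0),
                _rec("G1", "SYM", "T1", 4.0),
            ]
        )
        (tree,) = trees
        assert tree.gene_fpkm_reported == pytest.approx(10.0)
        assert tree.gene_fpkm_computed == pytest.approx(4.0)

    def test_duplicate_transcript_row_is_validation_error(self):
        with pytest.raises(ProbelinkError, match="CUFF.2094.1"):
            build_trees(CCND1 + [CCND1[1]])


class TestCheckGeneTotals:
    def test_consistent_gene_not_flagged(self):
        assert check_gene_totals(build_trees(CCND1), 1e-5) == []

    def test_partial_isoform_listing_flagged(self):
        trees = build_trees(
            [_rec("ENSG00000109685", "WHSC1", "ENST00000382891", 38.771, "55.1773")]
        )
        (disc,) = check_gene_totals(trees, 1e-5)
        assert disc.reported == pytest.approx(55.1773)
        assert disc.computed == pytest.approx(38.771)

    def test_absent_reported_never_flagged(self):
        trees = build_trees([_rec("G1", "S", "T1", 5.0)])
        assert check_gene_totals(trees, 1e-12) == []

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            check_gene_totals([], 0.0)


class TestDominantIsoform:
    def test_h929_whsc1(self):
        rows = [
            _rec("ENSG00000109685", "WHSC1", "ENST00000508355", 121.89),
            _rec("ENSG00000109685", "WHSC1", "CUFF.20684.17", 68.9562),
            _rec("ENSG00000109685", "WHSC1", "ENST00000382891", 58.5494),
        ]
        (tree,) = build_trees(rows)
        assert dominant_isoform(tree) == "ENST00000508355"

    def test_rpmi_fgfr3_dominant_is_novel(self):
        rows = [
            _rec("ENSG00000068078", "FGFR3", "CUFF.23217.9", 1.27549),
            _rec("ENSG00000068078", "FGFR3", "ENST00000340107", 1.24395),
            _rec("ENSG00000068078", "FGFR3", "ENST00000260795", 0.445095),
        ]
        (tree,) = build_trees(rows)
        assert dominant_isoform(tree) == "CUFF.23217.9"

    def test_tie_breaks_lexicographically(self):
        rows = [_rec("G", "S", "TB", 1.0), _rec("G", "S", "TA", 1.0)]
        (tree,) = build_trees(rows)
        assert dominant_isoform(tree) == "TA"

    def test_dominant_fpkm_is_maximal(self, h929_annotated):
        for tree in build_trees([a.record for a in h929_annotated]):
            if not tree.isoforms:
                continue
            dom = dominant_isoform(tree)
            dom_fpkm = next(i.fpkm for i in tree.isoforms if i.transcript_id == dom)
            assert all(dom_fpkm >= i.fpkm for i in tree.isoforms)


class TestNovelFraction:
    def test_ccnd1_hand_ratio(self):
        (tree,) = build_trees(CCND1)
        assert novel_fraction(tree) == pytest.approx(15.7855 / 42.73005, rel=1e-9)

    def test_all_known_gene_is_zero(self):
        (tree,) = build_trees([_rec("G", "S", "ENST1", 2.0)])
        assert novel_fraction(tree) == 0.0

    def test_all_novel_gene_is_one(self):
        (tree,) = build_trees([_rec("G", "S", "CUFF.1.1", 2.0)])
        assert novel_fraction(tree) == 1.0

    def test_zero_total_undefined(self):
        (tree,) = build_trees([_rec("G", "S", "T", 0.0)])
        assert novel_fraction(tree) is None

    @settings(max_examples=40, derandomize=True)
    @given(
        fpkms=st.lists(
            st.floats(min_value=0.0, max_value=1e4, allow_nan=False), min_size=1,
            max_size=8
        ),
        novel_mask=st.lists(st.booleans(), min_size=8, max_size=8),
    )
    def test_fraction_in_unit_interval(self, fpkms, novel_mask):
        rows = [
            _rec("G", "S", ("CUFF.1." if novel else "ENST") + str(i), f)
            for i, (f, novel) in enumerate(zip(fpkms, novel_mask))
        ]
        (tree,) = build_trees(rows)
        frac = novel_fraction(tree)
        if tree.gene_fpkm_computed <= 0:
            assert frac is None
        else:
            assert 0.0 <= frac <= 1.0
            if not any(i.is_novel for i in tree.isoforms):
                assert frac == 0.0


class TestNoveltyFlag:
    @pytest.mark.parametrize(
        "tid, expected",
        [
            ("CUFF.403.1", True),
            ("CUFF.23217.9", True),
            ("ENST00000373970", False),
            ("cuff.403.1", False),  # case-sensitive by convention
            ("XCUFF.1", False),
        ],
    )
    def test_literal_prefix(self, tid, expected):
        assert is_novel_transcript(tid) is expected

    def test_configurable_assembler_prefix(self):
        assert is_novel_transcript("STRG.5.1", novel_prefix="STRG.")


class TestLog2:
    def test_examples(self):
        assert log2_expression(1.0) == 0.0
        assert log2_expression(8.0) == 3.0
        # independent arithmetic: exp2 inverse
        value = log2_expression(42.7301)
        assert math.isclose(2.0**value, 42.7301, rel_tol=1e-12)
        assert value == pytest.approx(5.4172, abs=1e-4)

    def test_nonpositive_is_exclusion_signal_not_exception(self):
        assert log2_expression(0.0) is None
        assert log2_expression(-3.0) is None


def test_tree_text_marks_novel_isoforms():
    (tree,) = build_trees(CCND1)
    text = tree_as_text(tree)
    assert "CUFF.2094.1" in text and "*" in text
    assert text.splitlines()[0].startswith("CCND1")
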