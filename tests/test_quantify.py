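"""Gene lengths, RPKM, enrichment calling and report arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from equitx.datasets import EQUINE_COVERAGE_SPEC, SEVEN_TISSUE_READ_STATS, read_statistics_report
from equitx.io_formats import AnnotationSet
from equitx.quantify import (
    CountMatrix,
    CoverageSpec,
    EnrichmentConfig,
    ExpressionMatrix,
    count_from_assignments,
    coverage,
    enriched_genes,
    gene_length,
    gene_lengths,
    percent,
    read_counts_tsv,
    read_expression_tsv,
    rpkm,
    rpkm_matrix,
    write_counts_tsv,
    write_expression_tsv,
)

from conftest import tx


class TestGeneLength:
    def test_disjoint_exons_sum(self):
        ann = AnnotationSet([tx("t1", [(0, 100), (200, 300)], gene="g")])
        assert gene_length("g", ann) == 200

    def test_overlapping_transcripts_union(self):
        ann = AnnotationSet(
            [tx("t1", [(0, 100)], gene="g"), tx("t2", [(50, 150)], gene="g")]
        )
        assert gene_length("g", ann) == 150

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            gene_length("nope", AnnotationSet())

    def test_random_models_match_base_marking_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            transcripts = []
            for t in range(rng.integers(1, 4)):
                pos = int(rng.integers(0, 500))
                exons = []
                for _ in range(rng.integers(1, 5)):
                    length = int(rng.integers(10, 80))
                    exons.append((pos, pos + length))
                    pos += length + int(rng.integers(2, 50))
                transcripts.append(tx(f"t{t}", exons, gene="g"))
            ann = AnnotationSet(transcripts)
            marked = set()
            for t in transcripts:
                for s, e in t.exons:
                    marked.update(range(s, e))
            assert gene_length("g", ann) == len(marked)


class TestRpkm:
    def test_closed_form(self):
        assert rpkm(10, 10**6, 1000) == pytest.approx(10.0)
        assert rpkm(0, 123, 456) == 0.0

    def test_scale_invariance(self):
        assert rpkm(10, 10**6, 500) == pytest.approx(rpkm(20, 2 * 10**6, 500))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)

    def test_matrix_inversion_identity(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, (20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=list("ABCD"),
        )
        totals = pd.Series(counts.sum() + rng.integers(10, 100, 4), index=counts.columns)
        lengths = pd.Series(rng.integers(200, 3000, 20), index=counts.index)
        cm = CountMatrix(counts=counts, totals=totals)
        expr = rpkm_matrix(cm, lengths)
        back = (
            expr.rpkm
            * lengths.to_numpy()[:, None]
            * totals.to_numpy()[None, :]
            / 1e9
        )
        assert np.allclose(back.to_numpy(), counts.to_numpy())

    def test_tsv_round_trips(self, tmp_path):
        counts = pd.DataFrame([[3, 4], [0, 9]], index=["g1", "g2"], columns=["A", "B"])
        cm = CountMatrix(counts=counts, totals=pd.Series([10, 20], index=["A", "B"]))
        write_counts_tsv(cm, tmp_path / "c.tsv")
        back = read_counts_tsv(tmp_path / "c.tsv")
        assert back.counts.equals(cm.counts) and back.totals.equals(cm.totals)
        expr = rpkm_matrix(cm, pd.Series([100, 250], index=["g1", "g2"]))
        write_expression_tsv(expr, tmp_path / "e.tsv")
        back_e = read_expression_tsv(tmp_path / "e.tsv")
        assert np.allclose(back_e.rpkm.to_numpy(), expr.rpkm.to_numpy())


class TestCounting:
    def test_unique_filter_excludes_multihits_from_totals(self):
        ann = AnnotationSet([tx("t", [(0, 100)], gene="A")])
        rows = [("s1", "A", 1)] * 5 + [("s1", "A", 3)]
        cm = count_from_assignments(rows, ann)
        assert cm.counts.loc["A", "s1"] == 5 and cm.totals["s1"] == 5

    def test_ambiguous_reads_count_toward_totals_only(self):
        cm = count_from_assignments([("s1", None, 1)])
        assert cm.totals["s1"] == 1 and cm.counts.sum().sum() == 0

    def test_unknown_gene_rejected(self):
        ann = AnnotationSet([tx("t", [(0, 100)], gene="A")])
        with pytest.raises(KeyError):
            count_from_assignments([("s1", "B", 1)], ann)

    def test_matrix_totals_invariant(self):
        with pytest.raises(ValueError):
            CountMatrix(
                counts=pd.DataFrame({"s": [5]}, index=["g"]),
                totals=pd.Series({"s": 3}),
            )


def _expr(rows, samples=None):
    mat = pd.DataFrame(
        rows,
        index=[f"g{i}" for i in range(len(rows))],
        columns=samples or [f"s{j}" for j in range(len(rows[0]))],
    )
    return ExpressionMatrix(rpkm=mat, gene_lengths=pd.Series(1000, index=mat.index))


class TestEnrichment:
    def test_clear_single_sample_enrichment(self):
        out = enriched_genes(_expr([[60, 1, 1, 1, 1, 1, 1]]))
        assert out == [("g0", "s0")]

    def test_two_high_samples_block_each_other(self):
        assert enriched_genes(_expr([[100, 100, 0, 0, 0, 0, 0]])) == []

    def test_min_rpkm_floor(self):
        assert enriched_genes(_expr([[4, 0, 0, 0, 0, 0, 0]])) == []

    def test_strict_inequalities(self):
        # exactly 10x the mean of others, and exactly min_rpkm, both fail
        assert enriched_genes(_expr([[10, 1, 1, 1, 1, 1, 1]])) == []
        assert enriched_genes(_expr([[5, 0, 0, 0, 0, 0, 0]])) == []

    def test_single_sample_matrix_rejected(self):
        with pytest.raises(ValueError):
            enriched_genes(_expr([[10]]))

    def test_fold_criterion_scale_free_threshold_not(self):
        row = [[60, 1, 1, 1, 1, 1, 1]]
        assert enriched_genes(_expr([[v * 10 for v in row[0]]])) == [("g0", "s0")]
        assert enriched_genes(_expr([[v / 100 for v in row[0]]])) == []

    def test_mutual_exclusivity_randomized(self):
        rng = np.random.default_rng(123)
        x = rng.lognormal(1.5, 2.0, size=(20000, 7))
        x[rng.random(x.shape) < 0.3] = 0.0
        mat = pd.DataFrame(x, index=[f"g{i}" for i in range(len(x))], columns=list("ABCDEFG"))
        hits = enriched_genes(ExpressionMatrix(rpkm=mat, gene_lengths=pd.Series(1000, index=mat.index)))
        genes = [g for g, _ in hits]
        assert len(genes) == len(set(genes))


class TestReportArithmetic:
    @pytest.mark.parametrize(
        "reads,expect", [(7_856_017, 0.15), (12_708_499, 0.25), (0, 0.0)]
    )
    def test_coverage(self, reads, expect):
        assert coverage(reads, EQUINE_COVERAGE_SPEC) == pytest.approx(expect)

    @pytest.mark.parametrize(
        "num,den,expect",
        [(18_243_283, 20_853_992, 87), (27_746_321, 33_158_285, 84), (1, 2, 50)],
    )
    def test_percent(self, num, den, expect):
        assert percent(num, den) == expect

    def test_percent_zero_denominator(self):
        with pytest.raises(ValueError):
            percent(1, 0)

    @given(st.integers(0, 10**8), st.integers(1, 10**8))
    @settings(derandomize=True, max_examples=100)
    def test_percent_bounds_and_rounding(self, num, den):
        p = percent(num, den)
        assert abs(p - 100 * num / den) <= 0.5

    def test_seven_sample_report_columns(self):
        out = read_statistics_report()
        assert list(out["pct_raw_trimmed"]) == [87, 85, 87, 84, 86, 87, 88]
        assert list(out["pct_trimmed_aligned"]) == [43, 43, 44, 39, 43, 43, 47]
        assert list(out["avg_coverage"]) == [0.15, 0.23, 0.15, 0.21, 0.17, 0.18, 0.25]
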