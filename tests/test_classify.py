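"""Class-code assignment and consensus construction, cross-checked against
an index-free, base-resolution brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

from equitx.classify import (
    CLASS_CODES,
    build_consensus,
    classify_transcript,
    compare_sets,
    contained_compatible,
    intron_chain_equal,
    shares_junction,
    single_exon_match,
)
from equitx.io_formats import AnnotationSet
from equitx.synthetic import SimulationConfig, make_annotation, make_assembly_pair

from conftest import tx


# ---------------------------------------------------------------- oracle --

from functools import lru_cache


@lru_cache(maxsize=4096)
def _chain(t):
    return tuple((t.exons[i][1], t.exons[i + 1][0]) for i in range(len(t.exons) - 1))


@lru_cache(maxsize=4096)
def _bases(t):
    out = set()
    for s, e in t.exons:
        out.update(range(s, e))
    return out


def oracle_code(q, r, min_ro=0.8):
    """Brute-force pairwise code: exon overlap by explicit base sets,
    containment by subset tests, precedence applied in order."""
    if q.chrom != r.chrom:
        return None
    same = q.strand == r.strand
    qc, rc = _chain(q), _chain(r)
    qb, rb = _bases(q), _bases(r)
    if same and len(qc) >= 1 and len(rc) >= 1 and qc == rc:
        return "="
    if same and not qc and not rc:
        ov = len(qb & rb)
        if ov >= min_ro * len(qb) and ov >= min_ro * len(rb):
            return "="
    if same and q.start >= r.start and q.end <= r.end:
        if not qc:
            if any(qb <= set(range(s, e)) for s, e in r.exons):
                return "c"
        else:
            for k in range(len(rc) - len(qc) + 1):
                if rc[k : k + len(qc)] == qc:
                    first_ok = _bases(tx("f", [q.exons[0]], q.strand, q.chrom)) & set(
                        range(*r.exons[k])
                    )
                    last_ok = _bases(tx("l", [q.exons[-1]], q.strand, q.chrom)) & set(
                        range(*r.exons[k + len(qc)])
                    )
                    if first_ok and last_ok:
                        return "c"
    if same and qc and set(qc) & set(rc):
        return "j"
    if same and qb & rb:
        return "o"
    if any(d <= q.start and q.end <= a for d, a in rc):
        return "i"
    if not same and qb & rb:
        return "x"
    return None


def oracle_classify(q, refs, min_ro=0.8):
    best = None
    for r in refs:
        code = oracle_code(q, r, min_ro)
        if code is None:
            continue
        shared = len(set(_chain(q)) & set(_chain(r)))
        key = (CLASS_CODES.index(code), -shared, r.end - r.start, r.transcript_id)
        if best is None or key < best[0]:
            best = (key, code, r)
    if best is None:
        return "u", None
    return best[1], best[2]


# ------------------------------------------------------------ primitives --

class TestPrimitives:
    def test_identical_transcripts_match(self, ref_three_exon):
        assert intron_chain_equal(ref_three_exon, ref_three_exon)

    def test_terminal_ends_ignored(self, ref_three_exon):
        other = tx("q", [(150, 200), (300, 400), (500, 650)])
        assert intron_chain_equal(ref_three_exon, other)

    def test_single_exon_pairs_never_chain_equal(self):
        assert not intron_chain_equal(tx("a", [(0, 100)]), tx("b", [(0, 100)]))

    def test_chain_equality_is_symmetric_on_random_pairs(self):
        rng = np.random.default_rng(3)
        ann = list(make_annotation(SimulationConfig(seed=3, n_genes=30)))
        for _ in range(200):
            a, b = rng.choice(len(ann), 2)
            assert intron_chain_equal(ann[a], ann[b]) == intron_chain_equal(
                ann[b], ann[a]
            )

    @pytest.mark.parametrize(
        "b_exon,expect",
        [((0, 100), True), ((90, 200), False), ((10, 110), True), ((150, 250), False)],
    )
    def test_single_exon_match_arithmetic(self, b_exon, expect):
        a = tx("a", [(0, 100)])
        b = tx("b", [b_exon])
        assert single_exon_match(a, b) is expect

    def test_single_exon_match_randomized_against_arithmetic(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            s1, s2 = rng.integers(0, 100, 2)
            l1, l2 = rng.integers(10, 120, 2)
            a, b = tx("a", [(s1, s1 + l1)]), tx("b", [(s2, s2 + l2)])
            ov = min(s1 + l1, s2 + l2) - max(s1, s2)
            want = ov >= 0.8 * l1 and ov >= 0.8 * l2 and ov > 0
            assert single_exon_match(a, b) == want

    def test_containment_of_truncation(self, ref_three_exon):
        q = tx("q", [(350, 400), (500, 600)])  # starts inside ref's 2nd exon
        assert contained_compatible(q, ref_three_exon)

    def test_extension_past_reference_end_not_contained(self, ref_three_exon):
        q = tx("q", [(300, 400), (500, 700)])
        assert not contained_compatible(q, ref_three_exon)

    def test_intron_chain_mismatch_not_contained(self, ref_three_exon):
        q = tx("q", [(300, 390), (500, 600)])  # novel donor
        assert not contained_compatible(q, ref_three_exon)

    def test_shared_junction_detection(self, ref_three_exon):
        q = tx("q", [(150, 200), (300, 350)])
        assert shares_junction(q, ref_three_exon)
        assert not shares_junction(tx("s", [(100, 600)]), ref_three_exon)


# ------------------------------------------------------- classification --

class TestClassify:
    def test_identical_query_is_equals(self, small_annotation, ref_three_exon):
        assert classify_transcript(ref_three_exon, small_annotation).code == "="

    def test_no_reference_on_chrom_is_u(self, small_annotation):
        ct = classify_transcript(tx("q", [(0, 100)], chrom="chrZ"), small_annotation)
        assert ct.code == "u" and ct.best_ref is None

    def test_intronic_and_antisense(self, small_annotation):
        assert classify_transcript(tx("q", [(210, 290)]), small_annotation).code == "i"
        assert (
            classify_transcript(
                tx("q", [(120, 180)], strand="-"), small_annotation
            ).code
            == "x"
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_on_simulated_instances(self, seed):
        cfg = SimulationConfig(seed=seed, n_genes=30)
        ann = make_annotation(cfg)
        primary, secondary, _ = make_assembly_pair(ann, cfg)
        refs = list(primary)
        for q in secondary:
            got = classify_transcript(q, primary)
            code, ref = oracle_classify(q, refs)
            assert got.code == code
            assert (got.best_ref.transcript_id if got.best_ref else None) == (
                ref.transcript_id if ref else None
            )

    def test_planted_labels_recovered(self):
        cfg = SimulationConfig(seed=17, n_genes=120)
        ann = make_annotation(cfg)
        primary, secondary, truth = make_assembly_pair(ann, cfg)
        for q in secondary:
            assert (
                classify_transcript(q, primary).code
                == truth.transcript_classes[q.transcript_id]
            )

    def test_planted_u_has_no_overlap(self):
        cfg = SimulationConfig(seed=2, n_genes=80)
        ann = make_annotation(cfg)
        primary, secondary, truth = make_assembly_pair(ann, cfg)
        for q in secondary:
            if truth.transcript_classes[q.transcript_id] == "u":
                assert primary.overlapping(q.chrom, q.start, q.end) == []


# ------------------------------------------------------------ consensus --

class TestConsensus:
    def test_constructed_example(self, ref_three_exon):
        p2 = tx("p2", [(2000, 2100), (2500, 2600)])
        p3 = tx("p3", [(5000, 5100)])
        primary = AnnotationSet([ref_three_exon, p2, p3])
        secondary = AnnotationSet(
            [
                tx("s1", [(150, 200), (300, 400), (500, 550)]),  # = ref1
                tx("s2", [(2020, 2080)]),  # contained in p2's first exon
            ]
        )
        cons, rep = build_consensus(primary, secondary)
        assert set(cons.transcript_ids) == {"ref1", "p2"}
        # s1 both chain-matches and is contained in ref1, so the two
        # corroborating subsets overlap; the union is still 2
        assert (rep.n_chain_match, rep.n_containing, rep.n_consensus) == (1, 2, 2)

    def test_empty_secondary_gives_empty_consensus(self, small_annotation):
        cons, rep = build_consensus(small_annotation, AnnotationSet())
        assert len(cons) == 0 and rep.n_consensus == 0

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_consensus_equals_planted_membership(self, seed):
        cfg = SimulationConfig(seed=seed, n_genes=100)
        ann = make_annotation(cfg)
        primary, secondary, truth = make_assembly_pair(ann, cfg)
        cons, _ = build_consensus(primary, secondary)
        planted = {
            truth.partner[sid]
            for sid, code in truth.transcript_classes.items()
            if code in "=c"
        }
        assert set(cons.transcript_ids) == planted

    def test_enlarging_secondary_never_shrinks_consensus(self):
        cfg = SimulationConfig(seed=6, n_genes=60)
        ann = make_annotation(cfg)
        primary, secondary, _ = make_assembly_pair(ann, cfg)
        sec_list = list(secondary)
        half, _ = build_consensus(primary, AnnotationSet(sec_list[: len(sec_list) // 2]))
        full, _ = build_consensus(primary, secondary)
        assert set(half.transcript_ids) <= set(full.transcript_ids)
        assert set(full.transcript_ids) <= set(primary.transcript_ids)


# ---------------------------------------------------------- compare_sets --

class TestCompareSets:
    def test_self_comparison_concentrates_on_equals(self):
        cfg = SimulationConfig(seed=1, n_genes=40)
        ann = make_annotation(cfg)
        res = compare_sets(ann, ann)
        assert res.counts["="] == len(ann)
        assert sum(res.counts.values()) == len(ann)

    def test_disjoint_chromosomes_all_u(self, small_annotation):
        query = AnnotationSet([tx("q1", [(0, 100)], chrom="chr9")])
        res = compare_sets(query, small_annotation, reverse=True)
        assert res.counts["u"] == 1
        assert res.n_reference_without_overlap == len(small_annotation)

    def test_counts_partition_query(self):
        cfg = SimulationConfig(seed=8, n_genes=70)
        ann = make_annotation(cfg)
        primary, secondary, _ = make_assembly_pair(ann, cfg)
        res = compare_sets(secondary, primary)
        assert sum(res.counts.values()) == len(secondary)

    def test_planted_class_fractions_recovered(self):
        mix = (("=", 0.3), ("c", 0.0), ("j", 0.3), ("o", 0.0), ("i", 0.0), ("x", 0.0), ("u", 0.4))
        cfg = SimulationConfig(seed=12, n_genes=100, class_mix=mix)
        ann = make_annotation(cfg)
        primary, secondary, truth = make_assembly_pair(ann, cfg)
        res = compare_sets(secondary, primary)
        from collections import Counter

        planted = Counter(truth.transcript_classes.values())
        assert res.counts["j"] == planted["j"]
        assert res.counts["u"] == planted["u"]
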