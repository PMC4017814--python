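"""Transcript-set comparison: class codes, consensus construction, summaries.

A query transcript is labelled with a single-character class code describing
its best relationship to a reference set, using a reduced version of the
vocabulary popularised by cuffcompare/gffcompare:

    =   intron chain identical (terminal-exon ends ignored); for single-exon
        pairs, reciprocal overlap of at least ``min_reciprocal_overlap``
    c   contained in a reference transcript with a compatible intron
        structure (the query's intron chain is a contiguous sub-chain)
    j   novel isoform: shares at least one splice junction with a reference
        transcript but is neither = nor c
    o   generic same-strand exonic overlap
    i   query lies entirely within a reference intron
    x   exonic overlap on the opposite strand only
    u   no overlapping reference transcript

Exactly one code is assigned per query, by the fixed precedence
= > c > j > o > i > x > u. A consensus assembly keeps the transcripts of a
primary assembler that a secondary assembler corroborates — by intron-chain
match or by being contained/covered with compatible structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import AnnotationSet, TranscriptModel
from .junctions import introns_of

__all__ = [
    "CLASS_CODES",
    "ClassifiedTranscript",
    "ComparisonResult",
    "ConsensusReport",
    "intron_chain_equal",
    "single_exon_match",
    "contained_compatible",
    "shares_junction",
    "code_for_pair",
    "classify_transcript",
    "build_consensus",
    "compare_sets",
]

#: Class codes in precedence order, highest first.
CLASS_CODES: tuple[str, ...] = ("=", "c", "j", "o", "i", "x", "u")
_PRECEDENCE = {c: i for i, c in enumerate(CLASS_CODES)}

DEFAULT_SINGLE_EXON_OVERLAP = 0.8


@dataclass(frozen=True)
class ClassifiedTranscript:
    """A query transcript, its class code, and the reference transcript that
    produced the code (absent exactly when the code is 'u')."""

    query: TranscriptModel
    code: str
    best_ref: TranscriptModel | None

    def __post_init__(self) -> None:
        if (self.code == "u") != (self.best_ref is None):
            raise ValueError("best_ref must be None exactly for code 'u'")


def intron_chain_equal(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True iff both transcripts are multi-exon, colocated, and have the
    exact same intron chain; terminal exon boundaries are ignored."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.n_exons < 2 or b.n_exons < 2:
        return False
    return introns_of(a) == introns_of(b)


def single_exon_match(
    a: TranscriptModel,
    b: TranscriptModel,
    min_reciprocal_overlap: float = DEFAULT_SINGLE_EXON_OVERLAP,
) -> bool:
    """Single-exon analogue of '=': same chrom and strand, and the overlap
    covers at least ``min_reciprocal_overlap`` of BOTH exons."""
    if a.n_exons != 1 or b.n_exons != 1:
        return False
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    (a0, a1), (b0, b1) = a.exons[0], b.exons[0]
    overlap = min(a1, b1) - max(a0, b0)
    if overlap <= 0:
        return False
    return (
        overlap >= min_reciprocal_overlap * (a1 - a0)
        and overlap >= min_reciprocal_overlap * (b1 - b0)
    )


def _is_contiguous_subchain(sub: list, chain: list) -> int:
    """Offset at which ``sub`` occurs as a contiguous run of ``chain``, else -1.
    An empty ``sub`` matches nowhere (callers handle single-exon queries)."""
    if not sub or len(sub) > len(chain):
        return -1
    for k in range(len(chain) - len(sub) + 1):
        if chain[k : k + len(sub)] == sub:
            return k
    return -1


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0])


def contained_compatible(query: TranscriptModel, ref: TranscriptModel) -> bool:
    """True iff ``query`` is contained in ``ref`` with compatible introns.

    Requires the same chrom and strand, query span within ref span, and:
    single-exon query — its exon lies entirely within one ref exon;
    multi-exon query — its intron chain is a contiguous sub-chain of ref's
    and each terminal exon overlaps the corresponding ref exon.
    """
    if query.chrom != ref.chrom or query.strand != ref.strand:
        return False
    if query.start < ref.start or query.end > ref.end:
        return False
    if query.n_exons == 1:
        q0, q1 = query.exons[0]
        return any(s <= q0 and q1 <= e for s, e in ref.exons)
    k = _is_contiguous_subchain(introns_of(query), introns_of(ref))
    if k < 0:
        return False
    m = query.n_exons - 1  # introns in the query chain
    return (
        _intervals_overlap(query.exons[0], ref.exons[k]) > 0
        and _intervals_overlap(query.exons[-1], ref.exons[k + m]) > 0
    )


def shares_junction(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True iff the two transcripts share at least one intron (strand-aware)."""
    return bool(set(introns_of(a)) & set(introns_of(b)))


def _exon_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total overlapping bp between the two exon sets (chrom ignored)."""
    total = 0
    i = j = 0
    while i < a.n_exons and j < b.n_exons:
        ov = _intervals_overlap(a.exons[i], b.exons[j])
        if ov > 0:
            total += ov
        if a.exons[i][1] <= b.exons[j][1]:
            i += 1
        else:
            j += 1
    return total


def _within_one_intron(query: TranscriptModel, ref: TranscriptModel) -> bool:
    for i in range(ref.n_exons - 1):
        donor, acceptor = ref.exons[i][1], ref.exons[i + 1][0]
        if donor <= query.start and query.end <= acceptor:
            return True
    return False


def code_for_pair(
    query: TranscriptModel,
    ref: TranscriptModel,
    min_reciprocal_overlap: float = DEFAULT_SINGLE_EXON_OVERLAP,
) -> str | None:
    """The highest-precedence code applicable between one query and one
    reference transcript, or None when no relationship holds."""
    if query.chrom != ref.chrom:
        return None
    same_strand = query.strand == ref.strand
    if same_strand:
        if intron_chain_equal(query, ref) or single_exon_match(
            query, ref, min_reciprocal_overlap
        ):
            return "="
        if contained_compatible(query, ref):
            return "c"
        if query.n_exons > 1 and shares_junction(query, ref):
            return "j"
        if _exon_overlap_bp(query, ref) > 0:
            return "o"
    if _within_one_intron(query, ref):
        return "i"
    if not same_strand and _exon_overlap_bp(query, ref) > 0:
        return "x"
    return None


def classify_transcript(
    query: TranscriptModel,
    reference: AnnotationSet,
    min_reciprocal_overlap: float = DEFAULT_SINGLE_EXON_OVERLAP,
) -> ClassifiedTranscript:
    """Classify one query against a reference set.

    Candidate references are those whose span overlaps the query's on either
    strand. The best code wins by precedence; among references achieving it,
    ties break deterministically by (most shared introns, smallest span,
    lexicographic transcript_id).
    """
    candidates = reference.overlapping(query.chrom, query.start, query.end)
    best_code: str | None = None
    best_key: tuple | None = None
    best_ref: TranscriptModel | None = None
    q_introns = set(introns_of(query))
    for ref in candidates:
        code = code_for_pair(query, ref, min_reciprocal_overlap)
        if code is None:
            continue
        shared = len(q_introns & set(introns_of(ref)))
        key = (_PRECEDENCE[code], -shared, ref.end - ref.start, ref.transcript_id)
        if best_key is None or key < best_key:
            best_key = key
            best_code = code
            best_ref = ref
    if best_code is None:
        return ClassifiedTranscript(query, "u", None)
    return ClassifiedTranscript(query, best_code, best_ref)


@dataclass
class ConsensusReport:
    """Sizes of the two corroborating subsets and their union."""

    n_primary: int
    n_secondary: int
    n_chain_match: int  # primary with an intron-chain / single-exon match
    n_containing: int  # primary containing/covering a compatible secondary
    n_consensus: int  # union of the two subsets
    n_multi_exon: int  # consensus members with > 1 exon


def build_consensus(
    primary: AnnotationSet,
    secondary: AnnotationSet,
    min_reciprocal_overlap: float = DEFAULT_SINGLE_EXON_OVERLAP,
    include_reverse_containment: bool = False,
) -> tuple[AnnotationSet, ConsensusReport]:
    """Consensus assembly: the subset of ``primary`` corroborated by
    ``secondary``.

    A primary transcript t is kept when some secondary transcript s either
    matches it (intron_chain_equal, or single_exon_match for single-exon
    pairs) or is contained/covered by it with a compatible intron structure
    (contained_compatible(s, t)). With ``include_reverse_containment`` the
    relation t-contained-in-s also corroborates.
    """
    chain_match: set[str] = set()
    containing: set[str] = set()
    for t in primary:
        for s in secondary.overlapping(t.chrom, t.start, t.end, strand=t.strand):
            if t.transcript_id not in chain_match and (
                intron_chain_equal(t, s)
                or single_exon_match(t, s, min_reciprocal_overlap)
            ):
                chain_match.add(t.transcript_id)
            if t.transcript_id not in containing and (
                contained_compatible(s, t)
                or (
                    include_reverse_containment and contained_compatible(t, s)
                )
            ):
                containing.add(t.transcript_id)
            if t.transcript_id in chain_match and t.transcript_id in containing:
                break
    keep = chain_match | containing
    consensus = AnnotationSet(t for t in primary if t.transcript_id in keep)
    report = ConsensusReport(
        n_primary=len(primary),
        n_secondary=len(secondary),
        n_chain_match=len(chain_match),
        n_containing=len(containing),
        n_consensus=len(consensus),
        n_multi_exon=sum(1 for t in consensus if t.n_exons > 1),
    )
    return consensus, report


@dataclass
class ComparisonResult:
    """Per-transcript classification of a query set against a reference,
    with per-code counts (summing to the query size)."""

    classified: list[ClassifiedTranscript]
    counts: dict[str, int]
    n_reference: int
    n_reference_without_overlap: int | None = None

    @property
    def fraction_reference_without_overlap(self) -> float | None:
        if self.n_reference_without_overlap is None or self.n_reference == 0:
            return None
        return self.n_reference_without_overlap / self.n_reference


def compare_sets(
    query: AnnotationSet,
    reference: AnnotationSet,
    min_reciprocal_overlap: float = DEFAULT_SINGLE_EXON_OVERLAP,
    reverse: bool = False,
) -> ComparisonResult:
    """Classify every query transcript; optionally also count how many
    reference transcripts have no overlapping query on either strand."""
    classified = [
        classify_transcript(t, reference, min_reciprocal_overlap) for t in query
    ]
    counts = {c: 0 for c in CLASS_CODES}
    for ct in classified:
        counts[ct.code] += 1
    n_no_overlap = None
    if reverse:
        n_no_overlap = sum(
            1
            for r in reference
            if not query.overlapping(r.chrom, r.start, r.end)
        )
    return ComparisonResult(
        classified=classified,
        counts=counts,
        n_reference=len(reference),
        n_reference_without_overlap=n_no_overlap,
    )
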