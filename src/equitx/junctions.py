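"""Splice-junction extraction, deduplication and pooling.

Junction identity is the 4-tuple (chrom, donor, acceptor, strand); junctions
identical in coordinates but opposite in strand are distinct. Pooling is a
plain set union, so it is order-invariant, commutative, associative and
idempotent — the computational core of a two-pass alignment design where
junctions discovered per sample are pooled with the reference annotation's
before re-alignment.
"""

from __future__ import annotations

from typing import Iterable

from .io_formats import AnnotationSet, SpliceJunction, TranscriptModel

__all__ = ["introns_of", "junctions_of_set", "pool_junctions"]


def introns_of(t: TranscriptModel) -> list[SpliceJunction]:
    """The ordered intron chain of a transcript: for consecutive exons
    [a, b), [c, d) the junction is (donor=b, acceptor=c). Single-exon
    transcripts have none."""
    return [
        SpliceJunction(chrom=t.chrom, donor=t.exons[i][1], acceptor=t.exons[i + 1][0], strand=t.strand)
        for i in range(len(t.exons) - 1)
    ]


def junctions_of_set(annotation: AnnotationSet) -> set[SpliceJunction]:
    """Deduplicated junctions of every transcript in an annotation."""
    out: set[SpliceJunction] = set()
    for t in annotation:
        out.update(introns_of(t))
    return out


def pool_junctions(*sets: Iterable[SpliceJunction]) -> set[SpliceJunction]:
    """Non-redundant union of any number of junction collections."""
    pooled: set[SpliceJunction] = set()
    for s in sets:
        pooled.update(s)
    return pooled
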