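from __future__ import annotations

import pytest

from equitx.io_formats import AnnotationSet, QualityRead, TranscriptModel


def tx(
    tid: str,
    exons,
    strand: str = "+",
    chrom: str = "chr1",
    gene: str | None = None,
) -> TranscriptModel:
    """Shorthand transcript builder for tests."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or f"g_{tid}",
        chrom=chrom,
        strand=strand,
        exons=tuple(tuple(e) for e in exons),
    )


def qread(read_id: str, quals, bases: str | None = None) -> QualityRead:
    quals = tuple(quals)
    return QualityRead(read_id, bases if bases is not None else "A" * len(quals), quals)


@pytest.fixture
def ref_three_exon() -> TranscriptModel:
    """A 3-exon reference used across classification tests."""
    return tx("ref1", [(100, 200), (300, 400), (500, 600)])


@pytest.fixture
def small_annotation(ref_three_exon) -> AnnotationSet:
    return AnnotationSet(
        [
            ref_three_exon,
            tx("ref2", [(1000, 1200)], strand="-"),
            tx("ref3", [(50, 80), (250, 260)], chrom="chr2"),
        ]
    )
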