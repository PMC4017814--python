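"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open internally; conversion to and
from the 1-based inclusive GTF convention happens only at file boundaries.
FASTQ quality strings are Sanger Phred+33.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "QualityRead",
    "TranscriptModel",
    "AnnotationSet",
    "SpliceJunction",
    "FastqParseError",
    "GtfParseError",
    "read_fastq",
    "write_fastq",
    "read_gtf",
    "write_gtf",
    "read_juncs",
    "write_juncs",
]


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; message names the record index."""


class GtfParseError(ValueError):
    """Raised for GTF features violating basic coordinate sanity."""


@dataclass(frozen=True)
class QualityRead:
    """A sequencing read with per-base Phred qualities.

    ``bases`` is an uppercase string over {A, C, G, T, N}; ``quals`` holds one
    Phred integer in [0, 93] per base.
    """

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 or q > 93 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: Phred value outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, multi- or single-exon transcript on one chromosome.

    ``exons`` is a tuple of 0-based half-open ``(start, end)`` intervals,
    sorted by start, pairwise non-overlapping and non-adjacent (gap >= 1).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(
                    f"{self.transcript_id}: empty or inverted exon [{start}, {end})"
                )
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap, touch or are unsorted"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """One intron: ``donor`` is the 0-based first intronic base, ``acceptor``
    one past the last (half-open). Identity is strand-aware."""

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(f"junction donor {self.donor} >= acceptor {self.acceptor}")
        if self.strand not in ("+", "-"):
            raise ValueError("junction strand must be '+' or '-'")


class AnnotationSet:
    """A collection of transcripts with per-(chrom, strand) interval lookup.

    Transcript ids are unique within the set. The index maps genomic spans to
    transcripts and always covers exactly the transcripts held.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._by_id: dict[str, TranscriptModel] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._by_id:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self._by_id[t.transcript_id] = t
        self._trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
            t.start, t.end, t
        )

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._by_id.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self:
            seen.setdefault(t.gene_id, None)
        return list(seen)

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptModel]:
        hits = [t for t in self if t.gene_id == gene_id]
        if not hits:
            raise KeyError(gene_id)
        return hits

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[TranscriptModel]:
        """Transcripts whose span overlaps [start, end); both strands unless
        ``strand`` is given. Deterministic (transcript_id) order."""
        strands = (strand,) if strand else ("+", "-")
        hits = []
        for s in strands:
            tree = self._trees.get((chrom, s))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(start, end))
        return sorted(hits, key=lambda t: t.transcript_id)


def _decode_quals(qual_str: str) -> tuple[int, ...]:
    return tuple(ord(c) - 33 for c in qual_str)


def read_fastq(path: str | Path) -> Iterator[QualityRead]:
    """Stream QualityReads from a Sanger (Phred+33) FASTQ file, in file order.

    Malformed records raise :class:`FastqParseError` naming the record index.
    """
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            yield QualityRead(
                read_id=rec.id,
                bases=str(rec.seq).upper(),
                quals=tuple(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        n = locals().get("i", -1) + 1
        raise FastqParseError(f"malformed FASTQ record at index {n}: {exc}") from exc


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ. Returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")
            n += 1
    return n


@dataclass
class GtfReadStats:
    """Bookkeeping from :func:`read_gtf`."""

    transcripts: int = 0
    excluded_unstranded: int = 0
    rejected_inconsistent: int = 0


def read_gtf(
    path: str | Path, stats: GtfReadStats | None = None
) -> AnnotationSet:
    """Parse GTF2 exon features into an :class:`AnnotationSet`.

    1-based inclusive coordinates become 0-based half-open. Transcripts with
    strand '.' are excluded (and counted in ``stats`` / the log): downstream
    comparisons are defined for stranded transcripts only. A transcript whose
    exons sit on multiple chromosomes or strands is rejected with a warning.
    """
    stats = stats if stats is not None else GtfReadStats()
    exons: dict[str, list[tuple[str, str, str, int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            feat = feature_from_line(line, dialect=None)
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise GtfParseError(
                    f"{path} line {lineno}: exon end {feat.end} < start {feat.start}"
                )
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
            if tid not in exons:
                order.append(tid)
            exons.setdefault(tid, []).append(
                (gid, feat.seqid, feat.strand, feat.start - 1, feat.end)
            )

    annotation = AnnotationSet()
    for tid in order:
        rows = exons[tid]
        chroms = {r[1] for r in rows}
        strands = {r[2] for r in rows}
        if strands == {"."} or "." in strands and len(strands) == 1:
            stats.excluded_unstranded += 1
            continue
        if len(chroms) > 1 or len(strands) > 1:
            logger.warning(
                "transcript %s spans multiple chromosomes/strands; rejected", tid
            )
            stats.rejected_inconsistent += 1
            continue
        strand = rows[0][2]
        if strand == ".":
            stats.excluded_unstranded += 1
            continue
        ivs = sorted((s, e) for _, _, _, s, e in rows)
        annotation.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rows[0][0],
                chrom=rows[0][1],
                strand=strand,
                exons=tuple(ivs),
            )
        )
        stats.transcripts += 1
    if stats.excluded_unstranded:
        logger.info(
            "read_gtf(%s): excluded %d unstranded transcript(s)",
            path,
            stats.excluded_unstranded,
        )
    return annotation


def write_gtf(annotation: AnnotationSet, path: str | Path, source: str = "equitx") -> None:
    """Write one exon line per exon, 1-based inclusive, sorted by
    (chrom, start, transcript_id) — deterministic byte-for-byte."""
    lines = []
    for t in annotation:
        for i, (s, e) in enumerate(t.exons, 1):
            lines.append(
                (
                    t.chrom,
                    s,
                    t.transcript_id,
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}";\n',
                )
            )
    lines.sort(key=lambda x: (x[0], x[1], x[2]))
    with open(path, "w") as fh:
        for *_, text in lines:
            fh.write(text)


def write_juncs(junctions: Iterable[SpliceJunction], path: str | Path) -> int:
    """Write junctions in the raw-juncs dialect: ``chrom TAB left TAB right
    TAB strand`` where left = donor - 1 (last exonic base of the upstream
    exon) and right = acceptor (first exonic base of the downstream exon).
    Sorted, no duplicates. Returns the line count."""
    uniq = sorted(set(junctions))
    with open(path, "w") as fh:
        for j in uniq:
            fh.write(f"{j.chrom}\t{j.donor - 1}\t{j.acceptor}\t{j.strand}\n")
    return len(uniq)


def read_juncs(path: str | Path) -> set[SpliceJunction]:
    """Inverse of :func:`write_juncs`."""
    out: set[SpliceJunction] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                chrom, left, right, strand = line.rstrip("\n").split("\t")
                out.add(
                    SpliceJunction(
                        chrom=chrom,
                        donor=int(left) + 1,
                        acceptor=int(right),
                        strand=strand,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise GtfParseError(f"{path} line {lineno}: bad junction line") from exc
    return out
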