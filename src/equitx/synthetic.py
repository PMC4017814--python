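"""Planted-truth simulator for every input the pipeline consumes.

Real multi-tissue RNA-seq inputs (tens of millions of SOLiD reads, a 2.4 Gbp
genome) are replaced by desk-scale synthetic data with machine-readable
truth: annotations of non-overlapping gene loci, assembler-like transcript
pairs with planted class-code relationships, negative-binomial count
matrices with planted sample-enriched genes, and FASTQ reads built as a
high-quality core plus a degraded tail so the intended retained interval is
known in advance.

Every generator is a pure function of (config, seed): one pseudo-random
stream per generator, split from the master seed by a fixed label, so
adding a generator never perturbs the others' outputs. Class planting is
verified at generation time — a transcript planted as 'j' is checked not to
accidentally satisfy '=' or 'c' — so truth tables are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import AnnotationSet, QualityRead, TranscriptModel, write_fastq
from .classify import classify_transcript
from .quantify import CountMatrix
from .trimming import phred_to_error

import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "make_annotation",
    "make_assembly_pair",
    "make_counts",
    "make_reads",
]

# fixed per-generator stream labels under the master seed
_STREAM_ANNOTATION = 1
_STREAM_ASSEMBLY = 2
_STREAM_COUNTS = 3
_STREAM_READS = 4

_DEFAULT_CLASS_MIX: tuple[tuple[str, float], ...] = (
    ("=", 0.20),
    ("c", 0.20),
    ("j", 0.15),
    ("o", 0.15),
    ("i", 0.10),
    ("x", 0.10),
    ("u", 0.10),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All simulator knobs.

    The expression block mirrors the seven-sample study design (7 samples,
    strict 10x enrichment threshold downstream); reads are 50 bp, matching
    the SOLiD chemistry emulated in base space.
    """

    seed: int = 0
    # annotation
    n_genes: int = 100
    n_chromosomes: int = 4
    exon_count_range: tuple[int, int] = (2, 6)
    exon_length_range: tuple[int, int] = (100, 400)
    intron_length_range: tuple[int, int] = (200, 2000)
    intergenic_gap_range: tuple[int, int] = (1000, 5000)
    # assembler pair
    class_mix: tuple[tuple[str, float], ...] = _DEFAULT_CLASS_MIX
    terminal_jitter: int = 150
    # counts
    n_samples: int = 7
    nb_mean_range: tuple[float, float] = (20.0, 200.0)
    nb_dispersion: float = 0.1
    enriched_fraction: float = 0.05
    enriched_fold: float = 50.0
    unassigned_fraction: float = 0.1
    # reads
    n_reads: int = 500
    read_length: int = 50
    good_quality: int = 30
    bad_quality: int = 2
    tail_length_range: tuple[int, int] = (0, 15)
    n_rate: float = 0.01
    trim_limit: float = 0.2

    def __post_init__(self) -> None:
        probs = [p for _, p in self.class_mix]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("class_mix proportions must be >= 0 and sum to 1")
        for lo, hi in (
            self.exon_count_range,
            self.exon_length_range,
            self.intron_length_range,
            self.intergenic_gap_range,
            self.tail_length_range,
        ):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must satisfy 0 <= lo <= hi")
        if self.exon_count_range[0] < 1:
            raise ValueError("transcripts need >= 1 exon")
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples")
        if not 0 <= self.unassigned_fraction < 1:
            raise ValueError("unassigned_fraction in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        for key in (
            "exon_count_range",
            "exon_length_range",
            "intron_length_range",
            "intergenic_gap_range",
            "tail_length_range",
            "nb_mean_range",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "class_mix" in kwargs and isinstance(kwargs["class_mix"], Mapping):
            kwargs["class_mix"] = tuple(kwargs["class_mix"].items())
        return cls(**kwargs)


@dataclass
class TruthTable:
    """Machine-readable planted truth; each generator fills its own block."""

    # secondary transcript id -> planted class code; and its primary partner
    transcript_classes: dict[str, str] = field(default_factory=dict)
    partner: dict[str, str] = field(default_factory=dict)
    # planted enriched (gene, sample) pairs
    enriched_pairs: set[tuple[str, str]] = field(default_factory=set)
    # read id -> (kept, (start, end), reason)
    read_intervals: dict[str, tuple[bool, tuple[int, int], str]] = field(
        default_factory=dict
    )

    def classes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": list(self.transcript_classes),
                "planted_code": list(self.transcript_classes.values()),
                "partner": [self.partner.get(t, "") for t in self.transcript_classes],
            }
        )


def _randint(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def make_annotation(config: SimulationConfig) -> AnnotationSet:
    """Non-overlapping gene loci laid left to right on synthetic
    chromosomes, one transcript per gene. Deterministic given the seed."""
    rng = config.rng(_STREAM_ANNOTATION)
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chromosomes)}
    chroms = list(cursors)
    annotation = AnnotationSet()
    for g in range(config.n_genes):
        chrom = chroms[g % len(chroms)]
        pos = cursors[chrom] + _randint(rng, config.intergenic_gap_range)
        n_exons = _randint(rng, config.exon_count_range)
        exons = []
        for i in range(n_exons):
            if i > 0:
                pos += _randint(rng, config.intron_length_range)
            length = _randint(rng, config.exon_length_range)
            exons.append((pos, pos + length))
            pos += length
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{g:05d}"
        annotation.add(
            TranscriptModel(
                transcript_id=f"{gene_id}.T1",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
        )
        cursors[chrom] = pos
    return annotation


def _plant_secondary(
    t: TranscriptModel, code: str, rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[TranscriptModel, str] | None:
    """Build one secondary transcript bearing the planted relationship
    ``code`` to primary transcript ``t``. Returns (model, chrom-desert id)
    or None when the primary cannot host the code (caller redraws)."""
    exons = list(t.exons)
    k = len(exons)
    flip = {"+": "-", "-": "+"}

    if code == "=":
        if k < 2:
            return None
        jit_s = int(rng.integers(0, min(cfg.terminal_jitter, exons[0][1] - exons[0][0] - 1) + 1))
        jit_e = int(rng.integers(0, min(cfg.terminal_jitter, exons[-1][1] - exons[-1][0] - 1) + 1))
        new = exons.copy()
        new[0] = (exons[0][0] + jit_s, exons[0][1])
        new[-1] = (exons[-1][0], exons[-1][1] - jit_e)
        return TranscriptModel("", "", t.chrom, t.strand, tuple(new)), ""

    if code == "c":
        if k >= 2:
            m = int(rng.integers(1, k))  # number of exons in the fragment, < k
            i = int(rng.integers(0, k - m + 1))
            frag = exons[i : i + m]
        else:
            m, i = 1, 0
            frag = exons
        frag = list(frag)
        s0, e0 = frag[0]
        sN, eN = frag[-1]
        if m == 1:
            # single exon strictly inside one primary exon; for a single-exon
            # primary, shrink enough that the reciprocal-overlap '=' rule
            # cannot fire (overlap < 0.75 of the reference exon)
            width = e0 - s0
            if width < 40:
                return None
            lo = width // 8 + 1 if k == 1 else 1
            off = int(rng.integers(lo, width // 4 + 1))
            frag[0] = (s0 + off, e0 - off)
        else:
            frag[0] = (s0 + int(rng.integers(0, (e0 - s0) // 2 + 1)), e0)
            frag[-1] = (sN, eN - int(rng.integers(0, (eN - sN) // 2 + 1)))
        return TranscriptModel("", "", t.chrom, t.strand, tuple(frag)), ""

    if code == "j":
        if k < 2:
            return None
        # split the last exon with a novel intron; the first intron is shared
        s, e = exons[-1]
        if e - s < 80:
            return None
        cut = s + (e - s) // 3
        gap = 40
        new = exons[:-1] + [(s, cut), (cut + gap, e)]
        return TranscriptModel("", "", t.chrom, t.strand, tuple(new)), ""

    if code == "o":
        if k < 2:
            return None
        s, e = exons[0]
        intron_len = exons[1][0] - e
        reach = min(50, intron_len - 1)
        if reach < 1 or e - s < 50:
            return None
        return (
            TranscriptModel("", "", t.chrom, t.strand, ((e - 50, e + reach),)),
            "",
        )

    if code == "i":
        if k < 2:
            return None
        donor, acceptor = exons[0][1], exons[1][0]
        if acceptor - donor < 120:
            return None
        return (
            TranscriptModel("", "", t.chrom, t.strand, ((donor + 10, donor + 110),)),
            "",
        )

    if code == "x":
        s, e = exons[0]
        if e - s < 60:
            return None
        return (
            TranscriptModel("", "", t.chrom, flip[t.strand], ((s + 5, e - 5),)),
            "",
        )

    if code == "u":
        pos = int(rng.integers(0, 10_000))
        length = _randint(rng, cfg.exon_length_range)
        return (
            TranscriptModel("", "", "", t.strand, ((pos, pos + length),)),
            "chrU",
        )

    raise ValueError(f"unknown class code {code!r}")


def make_assembly_pair(
    annotation: AnnotationSet, config: SimulationConfig
) -> tuple[AnnotationSet, AnnotationSet, TruthTable]:
    """An assembler-like pair with planted class relationships.

    The primary set is the annotation re-labelled; each secondary transcript
    is planted against one primary per the class mix, label purity verified
    by classifying it against the primary set. Transcripts planted 'u' live
    on a reserved gene-desert chromosome.
    """
    rng = config.rng(_STREAM_ASSEMBLY)
    codes = [c for c, _ in config.class_mix]
    probs = np.array([p for _, p in config.class_mix], dtype=float)
    probs = probs / probs.sum()

    primary = AnnotationSet()
    prim_of: dict[str, TranscriptModel] = {}
    for i, t in enumerate(annotation):
        p = replace(
            t, transcript_id=f"PRI.{i + 1}", gene_id=f"PRI_G{i + 1}"
        )
        primary.add(p)
        prim_of[p.transcript_id] = p

    secondary = AnnotationSet()
    truth = TruthTable()
    desert_cursor = 0
    for i, pid in enumerate(primary.transcript_ids):
        p = prim_of[pid]
        code = str(rng.choice(codes, p=probs))
        planted = _plant_secondary(p, code, rng, config)
        attempts = 0
        while planted is None and attempts < 20:
            code = str(rng.choice(codes, p=probs))
            planted = _plant_secondary(p, code, rng, config)
            attempts += 1
        if planted is None:
            raise ValueError(
                "config ranges too tight to plant any class for "
                f"transcript {pid}"
            )
        model, desert = planted
        sid = f"SEC.{i + 1}"
        if desert:
            # shift onto a private stretch of the desert chromosome
            shift = desert_cursor + 5_000
            exons = tuple((s + shift, e + shift) for s, e in model.exons)
            desert_cursor = exons[-1][1]
            model = TranscriptModel(sid, f"SEC_G{i + 1}", "chrU", model.strand, exons)
        else:
            model = replace(model, transcript_id=sid, gene_id=f"SEC_G{i + 1}")
        got = classify_transcript(model, primary).code
        if got != code:
            raise AssertionError(
                f"planting failure: {sid} planted {code!r} classifies {got!r}"
            )
        secondary.add(model)
        truth.transcript_classes[sid] = code
        truth.partner[sid] = pid
    return primary, secondary, truth


def make_counts(
    annotation: AnnotationSet, config: SimulationConfig
) -> tuple[CountMatrix, TruthTable]:
    """Negative-binomial count matrix with planted sample-enriched genes.

    Counts are NB with variance mean + dispersion * mean^2 (Poisson at
    dispersion 0). A planted enriched (gene, sample) has its mean multiplied
    by ``enriched_fold`` in that sample only. Per-sample totals inflate the
    column sums by ``unassigned_fraction`` of uniquely aligned but
    unassigned reads.
    """
    rng = config.rng(_STREAM_COUNTS)
    genes = annotation.gene_ids
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    base = rng.uniform(*config.nb_mean_range, size=len(genes))
    means = np.tile(base[:, None], (1, len(samples)))

    truth = TruthTable()
    n_enriched = int(round(config.enriched_fraction * len(genes)))
    if n_enriched:
        picked = rng.choice(len(genes), size=n_enriched, replace=False)
        for gi in picked:
            si = int(rng.integers(0, len(samples)))
            means[gi, si] *= config.enriched_fold
            truth.enriched_pairs.add((genes[gi], samples[si]))

    if config.nb_dispersion == 0:
        counts = rng.poisson(means)
    else:
        n = 1.0 / config.nb_dispersion
        p = n / (n + means)
        counts = rng.negative_binomial(n, p)
    frame = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    colsums = frame.sum(axis=0).to_numpy(dtype=float)
    totals = np.ceil(colsums / (1.0 - config.unassigned_fraction)).astype(np.int64)
    return (
        CountMatrix(counts=frame, totals=pd.Series(totals, index=samples)),
        truth,
    )


def make_reads(
    config: SimulationConfig, path: str | Path | None = None
) -> tuple[list[QualityRead], TruthTable]:
    """Reads with a high-quality core and a degraded tail.

    Each read is ``read_length`` bp: the first ``read_length - tail`` bases
    at ``good_quality``, the tail at ``bad_quality``; Ns are injected at
    ``n_rate`` without changing the quality value. The truth records the
    interval the running-sum trimmer should retain — the full core, since
    good bases score limit - p > 0 and tail bases score < 0 — and whether
    the read survives the 20 bp / 2 N filters.
    """
    if phred_to_error(config.good_quality) >= config.trim_limit:
        raise ValueError("good_quality must beat the trim limit")
    if phred_to_error(config.bad_quality) <= config.trim_limit:
        raise ValueError("bad_quality must fall below the trim limit")
    rng = config.rng(_STREAM_READS)
    reads: list[QualityRead] = []
    truth = TruthTable()
    alphabet = np.array(list("ACGT"))
    for i in range(config.n_reads):
        rid = f"read{i + 1}"
        tail = _randint(rng, config.tail_length_range)
        tail = min(tail, config.read_length)
        core = config.read_length - tail
        bases = rng.choice(alphabet, size=config.read_length)
        n_mask = rng.random(config.read_length) < config.n_rate
        bases[n_mask] = "N"
        quals = np.full(config.read_length, config.good_quality, dtype=int)
        if tail:
            quals[core:] = config.bad_quality
        read = QualityRead(rid, "".join(bases), tuple(int(q) for q in quals))
        reads.append(read)

        interval = (0, core) if core > 0 else (0, 0)
        if core < 20:
            truth.read_intervals[rid] = (False, (0, 0), "too_short")
        elif int(n_mask[:core].sum()) > 2:
            truth.read_intervals[rid] = (False, (0, 0), "too_many_ambiguous")
        else:
            truth.read_intervals[rid] = (True, interval, "ok")
    if path is not None:
        write_fastq(reads, path)
    return reads, truth
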