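"""Quality trimming by the running-sum (modified Mott) algorithm, plus
ambiguity, adapter and length filters.

Each Phred score q maps to an error probability p = 10^(-q/10). For a
quality limit L (default 0.2) the running sum s_i = max(0, s_{i-1} + (L -
p_i)) is computed over the read; the retained segment ends at the running
sum's maximum and starts where the positive run containing that maximum
begins. A read whose maximum never leaves zero is discarded entirely.

Tie-breaks and the exact start rule:

* the RIGHTMOST position attaining the maximum is used, which retains the
  longest segment among score-equal choices;
* the start is the first position of the maximal run of positive sums
  containing the chosen maximum — this guarantees the retained segment's
  score Sum(L - p_i) equals max(s) even when the sum resets to zero between
  runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import QualityRead, read_fastq, write_fastq

__all__ = [
    "TrimConfig",
    "TrimResult",
    "TrimSummary",
    "phred_to_error",
    "quality_trim",
    "clip_adapters",
    "trim_read",
    "trim_fastq",
]


@dataclass(frozen=True)
class TrimConfig:
    """Trimming parameters.

    limit          error-probability threshold of the running sum (0 < limit < 1)
    max_ambiguous  maximum number of N bases permitted in a kept read
    min_length     minimum retained length in bp
    adapters       nucleotide strings clipped exactly from read ends
    """

    limit: float = 0.2
    max_ambiguous: int = 2
    min_length: int = 20
    adapters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.limit < 1:
            raise ValueError("limit must be in (0, 1)")
        if self.max_ambiguous < 0:
            raise ValueError("max_ambiguous must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class TrimResult:
    """Outcome for one read: kept or not, the retained half-open interval
    into the ORIGINAL read, and the reason when discarded."""

    read_id: str
    kept: bool
    retained: tuple[int, int]
    reason: str  # ok | too_short | too_many_ambiguous | adapter_only

    @property
    def length(self) -> int:
        return self.retained[1] - self.retained[0]


@dataclass
class TrimSummary:
    reads_in: int = 0
    reads_kept: int = 0
    retained_bp: int = 0

    @property
    def fraction_kept(self) -> float:
        return self.reads_kept / self.reads_in if self.reads_in else 0.0

    @property
    def mean_retained_length(self) -> float:
        return self.retained_bp / self.reads_kept if self.reads_kept else 0.0


def phred_to_error(q: float) -> float:
    """Error probability 10^(-q/10) of a Phred score; q must be >= 0."""
    if q < 0:
        raise ValueError(f"negative Phred score {q}")
    return 10.0 ** (-q / 10.0)


def quality_trim(read: QualityRead, limit: float = 0.2) -> tuple[int, int]:
    """Running-sum segment selection; returns a half-open interval into the
    read ((0, 0) when nothing survives)."""
    best_val = 0.0
    best_end = -1  # rightmost argmax of the running sum
    s = 0.0
    run_start = 0  # start of the current positive run
    run_start_at_best = 0
    for i, q in enumerate(read.quals):
        prev_zero = s == 0.0
        s += limit - phred_to_error(q)
        if s <= 0.0:
            s = 0.0
            continue
        if prev_zero:
            run_start = i
        if s >= best_val:  # >= keeps the rightmost maximum
            best_val = s
            best_end = i
            run_start_at_best = run_start
    if best_end < 0 or best_val <= 0.0:
        return (0, 0)
    return (run_start_at_best, best_end + 1)


def clip_adapters(bases: str, adapters: Sequence[str]) -> tuple[int, int]:
    """Exact-match adapter clipping at read ends, longest match first.

    Returns the half-open interval of the read that survives clipping. A
    prefix match removes the adapter and everything before it; a suffix match
    removes the adapter and everything after it.
    """
    lo, hi = 0, len(bases)
    for a in sorted(adapters, key=len, reverse=True):
        if not a:
            continue
        if bases.startswith(a, lo) and lo + len(a) <= hi:
            lo += len(a)
        if hi - len(a) >= lo and bases.endswith(a, lo, hi):
            hi -= len(a)
    return (lo, hi)


def trim_read(read: QualityRead, config: TrimConfig = TrimConfig()) -> TrimResult:
    """Adapter clip, then quality trim, then length and ambiguity filters."""
    lo, hi = clip_adapters(read.bases, config.adapters)
    if hi - lo == 0:
        return TrimResult(read.read_id, False, (0, 0), "adapter_only")
    inner = QualityRead(read.read_id, read.bases[lo:hi], read.quals[lo:hi])
    b, e = quality_trim(inner, config.limit)
    b, e = b + lo, e + lo
    if e - b < config.min_length:
        return TrimResult(read.read_id, False, (0, 0), "too_short")
    if read.bases.count("N", b, e) > config.max_ambiguous:
        return TrimResult(read.read_id, False, (0, 0), "too_many_ambiguous")
    return TrimResult(read.read_id, True, (b, e), "ok")


def trim_fastq(
    in_path: str | Path,
    out_path: str | Path,
    config: TrimConfig = TrimConfig(),
) -> TrimSummary:
    """Trim a FASTQ file, writing the retained parts of kept reads."""
    summary = TrimSummary()

    def kept_reads() -> Iterable[QualityRead]:
        for read in read_fastq(in_path):
            summary.reads_in += 1
            res = trim_read(read, config)
            if not res.kept:
                continue
            summary.reads_kept += 1
            summary.retained_bp += res.length
            b, e = res.retained
            yield QualityRead(read.read_id, read.bases[b:e], read.quals[b:e])

    write_fastq(kept_reads(), out_path)
    return summary
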