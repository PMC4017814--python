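"""Gene counting, RPKM, sample-enrichment calling and report arithmetic.

RPKM (reads per kilobase of gene model per million uniquely aligned reads)
is 1e9 * count / (total * gene_length). A gene is enriched in a sample when
its RPKM there exceeds ``min_rpkm`` (default 5) AND exceeds ``fold``
(default 10) times the mean RPKM over the other samples, zeros included.
Both inequalities are strict. With fold f over n samples and f/(n-1) > 1 no
gene can be enriched in more than one sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "EnrichmentConfig",
    "CoverageSpec",
    "ReadAssignment",
    "gene_length",
    "gene_lengths",
    "rpkm",
    "rpkm_matrix",
    "count_from_assignments",
    "enriched_genes",
    "coverage",
    "percent",
    "TOTALS_ROW",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_expression_tsv",
    "read_expression_tsv",
]


@dataclass
class CountMatrix:
    """Integer read counts per (gene, sample) plus per-sample totals of
    uniquely aligned reads. Totals may exceed the column sums because
    uniquely aligned but unassigned (ambiguous/intergenic) reads count
    toward the denominator but to no gene."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    totals: pd.Series  # per sample

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.totals = self.totals.astype(np.int64).reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        colsums = self.counts.sum(axis=0)
        if (self.totals < colsums).any():
            raise ValueError("per-sample total below the sum of gene counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpressionMatrix:
    """RPKM values per (gene, sample) with the gene lengths used."""

    rpkm: pd.DataFrame  # genes x samples, non-negative reals
    gene_lengths: pd.Series  # bp per gene

    def __post_init__(self) -> None:
        self.gene_lengths = self.gene_lengths.reindex(self.rpkm.index)
        if self.gene_lengths.isna().any():
            raise ValueError("missing gene length")
        if (self.gene_lengths < 1).any():
            raise ValueError("gene lengths must be >= 1 bp")
        if not np.isfinite(self.rpkm.to_numpy()).all():
            raise ValueError("non-finite RPKM")

    @property
    def genes(self) -> list[str]:
        return list(self.rpkm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.rpkm.columns)


@dataclass(frozen=True)
class EnrichmentConfig:
    """min_rpkm: expression floor within the test sample; fold: multiplier
    over the mean RPKM of the other samples."""

    min_rpkm: float = 5.0
    fold: float = 10.0

    def __post_init__(self) -> None:
        if self.min_rpkm <= 0:
            raise ValueError("min_rpkm must be > 0")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")


@dataclass(frozen=True)
class CoverageSpec:
    """Genome size and mean read length used for average-coverage arithmetic.
    Defaults are the equine reference values: 2,428,790,173 bp and 47 bp."""

    genome_size: int = 2_428_790_173
    mean_read_length: float = 47.0

    def __post_init__(self) -> None:
        if self.genome_size <= 0 or self.mean_read_length <= 0:
            raise ValueError("genome_size and mean_read_length must be positive")


@dataclass(frozen=True)
class ReadAssignment:
    """One read's alignment outcome: the sample it came from, the gene it
    was assigned to (None when ambiguous or intergenic) and its number of
    alignment hits (1 = unique)."""

    sample: str
    gene: str | None
    n_hits: int


def _merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def gene_length(gene_id: str, annotation: AnnotationSet) -> int:
    """Length of the union of all exon intervals across the gene's
    transcripts (the RPKM denominator)."""
    transcripts = annotation.transcripts_of_gene(gene_id)
    return _merged_length(iv for t in transcripts for iv in t.exons)


def gene_lengths(annotation: AnnotationSet) -> pd.Series:
    """Exon-union length for every gene in the annotation."""
    per_gene: dict[str, list[tuple[int, int]]] = {}
    for t in annotation:
        per_gene.setdefault(t.gene_id, []).extend(t.exons)
    return pd.Series(
        {g: _merged_length(ivs) for g, ivs in per_gene.items()}, dtype=np.int64
    )


def rpkm(count: float, total: float, length: float) -> float:
    """1e9 * count / (total * length)."""
    if total <= 0:
        raise ValueError("total uniquely aligned reads must be > 0")
    if length <= 0:
        raise ValueError("gene length must be > 0")
    return 1e9 * count / (total * length)


def rpkm_matrix(counts: CountMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Convert a count matrix to RPKM using per-gene exon-union lengths."""
    lengths = lengths.reindex(counts.counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:3])
        raise KeyError(f"no length for gene(s) {missing}")
    if (counts.totals <= 0).any():
        raise ValueError("every sample needs a positive total")
    vals = (
        1e9
        * counts.counts.to_numpy(dtype=float)
        / (
            counts.totals.to_numpy(dtype=float)[None, :]
            * lengths.to_numpy(dtype=float)[:, None]
        )
    )
    return ExpressionMatrix(
        rpkm=pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns),
        gene_lengths=lengths.astype(np.int64),
    )


def count_from_assignments(
    assignments: Iterable[ReadAssignment | tuple],
    annotation: AnnotationSet | None = None,
    samples: Sequence[str] | None = None,
) -> CountMatrix:
    """Tabulate per-gene counts from per-read assignment records.

    Reads with ``n_hits != 1`` are excluded from counts AND totals (the
    unique-alignment filter). Uniquely aligned reads with no gene contribute
    to totals only. When ``annotation`` is given, gene ids are validated
    against it and the matrix covers all its genes.
    """
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    known = set(annotation.gene_ids) if annotation is not None else None
    for a in assignments:
        if not isinstance(a, ReadAssignment):
            a = ReadAssignment(*a)
        totals.setdefault(a.sample, 0)
        if a.n_hits != 1:
            continue
        totals[a.sample] += 1
        if a.gene is None:
            continue
        if known is not None and a.gene not in known:
            raise KeyError(f"unknown gene id {a.gene!r}")
        counts.setdefault(a.gene, {})[a.sample] = (
            counts.setdefault(a.gene, {}).get(a.sample, 0) + 1
        )
    sample_order = list(samples) if samples is not None else sorted(totals)
    gene_order = (
        list(annotation.gene_ids) if annotation is not None else sorted(counts)
    )
    mat = pd.DataFrame(0, index=gene_order, columns=sample_order, dtype=np.int64)
    for g, per_sample in counts.items():
        for s, n in per_sample.items():
            mat.loc[g, s] = n
    tot = pd.Series({s: totals.get(s, 0) for s in sample_order}, dtype=np.int64)
    return CountMatrix(counts=mat, totals=tot)


def enriched_genes(
    expr: ExpressionMatrix | pd.DataFrame,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[tuple[str, str]]:
    """(gene, sample) pairs where rpkm > min_rpkm and rpkm > fold x the mean
    RPKM of the OTHER samples (zeros included in that mean)."""
    mat = expr.rpkm if isinstance(expr, ExpressionMatrix) else expr
    n = mat.shape[1]
    if n < 2:
        raise ValueError("enrichment needs at least two samples")
    x = mat.to_numpy(dtype=float)
    mean_others = (x.sum(axis=1, keepdims=True) - x) / (n - 1)
    hits = (x > config.min_rpkm) & (x > config.fold * mean_others)
    gi, si = np.nonzero(hits)
    return [(mat.index[g], mat.columns[s]) for g, s in zip(gi, si)]


#: Reserved row name carrying per-sample uniquely-aligned totals in count TSVs.
TOTALS_ROW = "__aligned_total__"


def write_counts_tsv(counts: CountMatrix, path) -> None:
    """Counts as TSV: gene_id column, one column per sample, plus a reserved
    ``__aligned_total__`` row holding the per-sample totals."""
    out = counts.counts.copy()
    out.loc[TOTALS_ROW] = counts.totals
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> CountMatrix:
    """Inverse of :func:`write_counts_tsv`."""
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    if TOTALS_ROW not in frame.index:
        raise ValueError(f"count table lacks the {TOTALS_ROW!r} row")
    totals = frame.loc[TOTALS_ROW]
    return CountMatrix(counts=frame.drop(index=TOTALS_ROW), totals=totals)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """RPKM as TSV: gene_id, gene length, one column per sample."""
    out = expr.rpkm.copy()
    out.insert(0, "length", expr.gene_lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path) -> ExpressionMatrix:
    """Inverse of :func:`write_expression_tsv`."""
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length" not in frame.columns:
        raise ValueError("expression table lacks the 'length' column")
    return ExpressionMatrix(
        rpkm=frame.drop(columns="length"), gene_lengths=frame["length"]
    )


def _round_half_away(x: float, ndigits: int = 0) -> float:
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def coverage(aligned_reads: int, spec: CoverageSpec = CoverageSpec()) -> float:
    """Average genome coverage, reads x read length / genome size, rounded
    half-away-from-zero to two decimals."""
    return _round_half_away(
        aligned_reads * spec.mean_read_length / spec.genome_size, 2
    )


def percent(numerator: float, denominator: float) -> int:
    """Nearest-integer percentage, half away from zero."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return int(_round_half_away(100.0 * numerator / denominator, 0))
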