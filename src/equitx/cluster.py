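"""Hierarchical clustering of sample expression profiles with bootstrap
support.

Samples are clustered by complete linkage on Euclidean distances between
their expression columns (RPKMs by default; a log2(x+1) transform is
available behind a flag). Clade support comes in two flavours:

* BP — the plain bootstrap probability: genes are resampled with
  replacement and bp(clade) is the fraction of bootstrap trees containing
  the clade's exact leaf set.
* AU — the approximately unbiased p-value from the multiscale bootstrap:
  bootstrap at several resample sizes r * n_genes, convert each bp_r to a
  probit z_r = Phi^-1(1 - bp_r), fit z_r = v*sqrt(r) + c/sqrt(r) by least
  squares, and report au = 1 - Phi(v - c). Clades whose bp_r is 0 or 1 at
  every scale cannot be fitted and inherit their plain bootstrap value.

Agglomeration ties break deterministically on the smallest lexicographic
merged leaf set, so identical inputs give identical trees on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .quantify import ExpressionMatrix

__all__ = [
    "ClusterNode",
    "SupportedDendrogram",
    "DEFAULT_SCALES",
    "sample_distance",
    "complete_linkage",
    "bootstrap_support",
    "au_support",
]

#: Multiscale-bootstrap resampling fractions, 0.5 to 1.4 step 0.1.
DEFAULT_SCALES: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


@dataclass
class ClusterNode:
    """A node of the merge tree. Leaves have height 0 and no children;
    internal nodes carry the linkage height and, once computed, bp/au
    support values in [0, 1]."""

    leaves: frozenset[str]
    height: float = 0.0
    children: tuple["ClusterNode", "ClusterNode"] | None = None
    bp: float | None = None
    au: float | None = None
    au_degenerate: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def walk(self) -> Iterable["ClusterNode"]:
        yield self
        if self.children:
            for c in self.children:
                yield from c.walk()


@dataclass
class SupportedDendrogram:
    """Binary merge tree over samples with optional per-clade support."""

    root: ClusterNode
    samples: tuple[str, ...]

    @property
    def internal_nodes(self) -> list[ClusterNode]:
        return [n for n in self.root.walk() if not n.is_leaf]

    @property
    def clades(self) -> set[frozenset[str]]:
        return {n.leaves for n in self.internal_nodes}

    def node(self, leaves: Iterable[str]) -> ClusterNode:
        target = frozenset(leaves)
        for n in self.root.walk():
            if n.leaves == target:
                return n
        raise KeyError(f"no node with leaf set {sorted(target)}")

    def to_newick(self, support: bool = True) -> str:
        def fmt(n: ClusterNode, parent_height: float) -> str:
            length = parent_height - n.height
            if n.is_leaf:
                (name,) = n.leaves
                return f"{name}:{length:.6g}"
            inner = ",".join(
                fmt(c, n.height)
                for c in sorted(n.children, key=lambda c: min(c.leaves))
            )
            label = ""
            if support and n.bp is not None:
                au = n.au if n.au is not None else n.bp
                label = f"{round(100 * au)}/{round(100 * n.bp)}"
            return f"({inner}){label}:{length:.6g}"

        return fmt(self.root, self.root.height) + ";"

    def support_table(self) -> pd.DataFrame:
        rows = [
            {
                "leaves": ",".join(sorted(n.leaves)),
                "height": n.height,
                "bp": n.bp,
                "au": n.au,
                "au_degenerate": n.au_degenerate,
            }
            for n in sorted(self.internal_nodes, key=lambda n: (n.height, sorted(n.leaves)))
        ]
        return pd.DataFrame(rows)


def _expr_values(expr: ExpressionMatrix | pd.DataFrame, log2: bool) -> tuple[np.ndarray, list[str]]:
    mat = expr.rpkm if isinstance(expr, ExpressionMatrix) else expr
    x = mat.to_numpy(dtype=float)
    if log2:
        x = np.log2(x + 1.0)
    return x, list(mat.columns)


def sample_distance(
    expr: ExpressionMatrix | pd.DataFrame, log2_transform: bool = False
) -> pd.DataFrame:
    """Euclidean distances between sample columns over all genes."""
    x, samples = _expr_values(expr, log2_transform)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    d = squareform(pdist(x.T, metric="euclidean"))
    return pd.DataFrame(d, index=samples, columns=samples)


def _agglomerate(dist: np.ndarray, labels: Sequence[str]) -> ClusterNode:
    """Naive complete-linkage agglomeration with lexicographic tie-break."""
    nodes = [ClusterNode(leaves=frozenset([lab])) for lab in labels]
    keys = [(lab,) for lab in labels]  # sorted leaf tuple per active cluster
    d = dist.astype(float).copy()
    active = list(range(len(labels)))
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                cand = (d[a, b], tuple(sorted(keys[a] + keys[b])))
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        (h, _), a, b = best
        merged = ClusterNode(
            leaves=nodes[a].leaves | nodes[b].leaves,
            height=h,
            children=(nodes[a], nodes[b]),
        )
        # complete linkage: distance to the merge is the max of the parts
        for k in active:
            if k not in (a, b):
                dm = max(d[a, k], d[b, k])
                d[a, k] = d[k, a] = dm
        nodes[a] = merged
        keys[a] = tuple(sorted(keys[a] + keys[b]))
        active.remove(b)
    return nodes[active[0]]


def complete_linkage(dist: pd.DataFrame) -> SupportedDendrogram:
    """Complete-linkage dendrogram from a symmetric distance table."""
    labels = list(dist.columns)
    root = _agglomerate(dist.to_numpy(dtype=float), labels)
    return SupportedDendrogram(root=root, samples=tuple(labels))


def _tree_clades(x: np.ndarray, samples: Sequence[str]) -> set[frozenset[str]]:
    d = squareform(pdist(x.T, metric="euclidean"))
    root = _agglomerate(d, samples)
    return {n.leaves for n in root.walk() if n.children is not None}


def _bp_at_scale(
    x: np.ndarray,
    samples: Sequence[str],
    clades: list[frozenset[str]],
    n_boot: int,
    resample_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    hits = np.zeros(len(clades))
    n_genes = x.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, resample_size)
        boot = _tree_clades(x[idx], samples)
        for i, c in enumerate(clades):
            if c in boot:
                hits[i] += 1
    return hits / n_boot


def bootstrap_support(
    expr: ExpressionMatrix | pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    log2_transform: bool = False,
) -> SupportedDendrogram:
    """Cluster the samples and attach plain bootstrap (BP) support.

    Genes are resampled with replacement ``n_boot`` times; bp(clade) is the
    fraction of bootstrap trees containing the clade's exact leaf set.
    Reproducible given ``seed``.
    """
    x, samples = _expr_values(expr, log2_transform)
    if len(samples) < 3:
        raise ValueError("bootstrap support needs at least three samples")
    tree = complete_linkage(sample_distance(expr, log2_transform))
    rng = np.random.default_rng(seed)
    nodes = tree.internal_nodes
    bp = _bp_at_scale(x, samples, [n.leaves for n in nodes], n_boot, x.shape[0], rng)
    for n, v in zip(nodes, bp):
        n.bp = float(v)
    return tree


def au_support(
    expr: ExpressionMatrix | pd.DataFrame,
    scales: Sequence[float] = DEFAULT_SCALES,
    n_boot_per_scale: int = 1000,
    seed: int | None = None,
    log2_transform: bool = False,
) -> SupportedDendrogram:
    """Cluster the samples and attach AU and BP support via the multiscale
    bootstrap.

    For each scale r the genes are resampled with size round(r * n_genes),
    giving per-clade bootstrap probabilities bp_r. Scales with 0 < bp_r < 1
    enter a least-squares probit fit z_r = v*sqrt(r) + c/sqrt(r) and
    au = 1 - Phi(v - c). Clades degenerate at every scale (bp_r all 0 or
    all 1), or with fewer than two usable scales, keep au = bp at scale 1
    and are flagged ``au_degenerate``. BP is reported from the scale closest
    to 1.
    """
    scales = tuple(scales)
    if len(scales) < 3:
        raise ValueError("need at least three scales")
    x, samples = _expr_values(expr, log2_transform)
    if len(samples) < 3:
        raise ValueError("bootstrap support needs at least three samples")
    tree = complete_linkage(sample_distance(expr, log2_transform))
    nodes = tree.internal_nodes
    clades = [n.leaves for n in nodes]
    rng = np.random.default_rng(seed)
    n_genes = x.shape[0]
    bp_by_scale = np.empty((len(scales), len(clades)))
    for si, r in enumerate(scales):
        size = max(1, round(r * n_genes))
        bp_by_scale[si] = _bp_at_scale(
            x, samples, clades, n_boot_per_scale, size, rng
        )
    scale1 = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    for ci, node in enumerate(nodes):
        bps = bp_by_scale[:, ci]
        node.bp = float(bps[scale1])
        usable = (bps > 0) & (bps < 1)
        if usable.sum() < 2:
            node.au = node.bp
            node.au_degenerate = True
            continue
        r = np.asarray(scales)[usable]
        z = norm.ppf(1.0 - bps[usable])
        design = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        (v, c), *_ = np.linalg.lstsq(design, z, rcond=None)
        node.au = float(np.clip(1.0 - norm.cdf(v - c), 0.0, 1.0))
    return tree
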