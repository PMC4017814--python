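"""End-to-end pipeline: trim -> junction pooling -> consensus -> reference
comparison -> RPKM -> enrichment -> clustering.

The run is driven by one declarative config (a mapping, usually loaded from
YAML). Every stage is listed explicitly with an ``enabled`` flag — stages
cannot be skipped silently — and each stage's parameters and outputs are
logged to a run-local file. A run is fully reproducible from its config and
seed; the summary report carries the read-statistics block (reads in/kept,
percent kept, average coverage for a given genome size and read length) and
the class-code count block.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import classify as _classify
from . import cluster as _cluster
from . import quantify as _quantify
from .io_formats import read_gtf, write_gtf, write_juncs
from .junctions import junctions_of_set, pool_junctions
from .synthetic import SimulationConfig, make_annotation, make_assembly_pair, make_counts, make_reads
from .trimming import TrimConfig, trim_fastq

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline"]

_STAGES = ("trim", "junctions", "consensus", "compare", "rpkm", "enrich", "cluster")


class PipelineError(ValueError):
    """Configuration or input problem detected before/during a run."""


def _stage_cfg(config: Mapping, name: str) -> tuple[bool, dict]:
    stages = config.get("stages", {})
    cfg = dict(stages.get(name, {}))
    enabled = bool(cfg.pop("enabled", True))
    return enabled, cfg


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict:
    """Run the enabled stages into ``outdir``; returns the summary report.

    ``config`` keys: ``seed`` (int), ``simulate`` (simulator overrides; when
    present all inputs are generated), ``inputs`` (paths to reads/primary/
    secondary/reference GTFs and a counts TSV), ``stages`` (per-stage
    ``enabled`` + parameters), ``report`` (genome_size, read_length).
    Inputs named in the config are checked before any stage runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("equitx")
    root.addHandler(handler)
    try:
        return _run(dict(config), outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: dict, outdir: Path) -> dict:
    seed = int(config.get("seed", 0))
    summary: dict[str, Any] = {"seed": seed, "outdir": str(outdir)}
    inputs = dict(config.get("inputs", {}))

    if "simulate" in config:
        sim_over = dict(config.get("simulate") or {})
        sim_over.setdefault("seed", seed)
        sim = SimulationConfig.from_dict(sim_over)
        simdir = outdir / "sim"
        simdir.mkdir(exist_ok=True)
        logger.info("simulate: %s", sim)
        annotation = make_annotation(sim)
        primary, secondary, truth = make_assembly_pair(annotation, sim)
        counts, counts_truth = make_counts(annotation, sim)
        make_reads(sim, simdir / "reads.fastq")
        write_gtf(annotation, simdir / "annotation.gtf")
        write_gtf(primary, simdir / "primary.gtf")
        write_gtf(secondary, simdir / "secondary.gtf")
        _quantify.write_counts_tsv(counts, simdir / "counts.tsv")
        truthdir = simdir / "truth"
        truthdir.mkdir(exist_ok=True)
        truth.classes_frame().to_csv(truthdir / "classes.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(counts_truth.enriched_pairs), columns=["gene_id", "sample"]
        ).to_csv(truthdir / "enriched.tsv", sep="\t", index=False)
        inputs = {
            "reads": simdir / "reads.fastq",
            "primary": simdir / "primary.gtf",
            "secondary": simdir / "secondary.gtf",
            "reference": simdir / "annotation.gtf",
            "counts": simdir / "counts.tsv",
        }
        summary["simulated"] = True

    required = {
        "trim": ["reads"],
        "junctions": ["primary", "secondary"],
        "consensus": ["primary", "secondary"],
        "compare": ["primary", "reference"],
        "rpkm": ["counts", "reference"],
        "enrich": ["counts", "reference"],
        "cluster": ["counts", "reference"],
    }
    for stage in _STAGES:
        enabled, _ = _stage_cfg(config, stage)
        if not enabled:
            continue
        for key in required[stage]:
            path = inputs.get(key)
            if path is None or not Path(path).exists():
                raise PipelineError(
                    f"stage {stage!r} needs input {key!r} "
                    f"({'missing from config' if path is None else path})"
                )

    enabled, cfg = _stage_cfg(config, "trim")
    summary["stages"] = {s: _stage_cfg(config, s)[0] for s in _STAGES}
    if enabled:
        tc = TrimConfig(
            limit=float(cfg.get("limit", 0.2)),
            max_ambiguous=int(cfg.get("max_ambiguous", 2)),
            min_length=int(cfg.get("min_length", 20)),
            adapters=tuple(cfg.get("adapters", ())),
        )
        logger.info("trim: %s", tc)
        ts = trim_fastq(inputs["reads"], outdir / "trimmed.fastq", tc)
        summary["trim"] = {
            "reads_in": ts.reads_in,
            "reads_kept": ts.reads_kept,
            "pct_kept": _quantify.percent(ts.reads_kept, ts.reads_in)
            if ts.reads_in
            else 0,
            "mean_retained_length": round(ts.mean_retained_length, 2),
        }
        report_cfg = config.get("report", {})
        if report_cfg.get("genome_size"):
            spec = _quantify.CoverageSpec(
                genome_size=int(report_cfg["genome_size"]),
                mean_read_length=float(
                    report_cfg.get("read_length", ts.mean_retained_length or 1)
                ),
            )
            summary["trim"]["avg_coverage_if_all_aligned"] = _quantify.coverage(
                ts.reads_kept, spec
            )

    annotations: dict[str, Any] = {}

    def gtf(key: str):
        if key not in annotations:
            annotations[key] = read_gtf(inputs[key])
        return annotations[key]

    enabled, cfg = _stage_cfg(config, "junctions")
    if enabled:
        pooled = pool_junctions(
            junctions_of_set(gtf("primary")), junctions_of_set(gtf("secondary"))
        )
        n = write_juncs(pooled, outdir / "pooled.juncs")
        logger.info("junctions: %d pooled non-redundant sites", n)
        summary["junctions"] = {"n_pooled": n}

    consensus_set = None
    enabled, cfg = _stage_cfg(config, "consensus")
    if enabled:
        consensus_set, rep = _classify.build_consensus(
            gtf("primary"),
            gtf("secondary"),
            include_reverse_containment=bool(cfg.get("include_reverse", False)),
        )
        write_gtf(consensus_set, outdir / "consensus.gtf")
        summary["consensus"] = {
            "n_primary": rep.n_primary,
            "n_secondary": rep.n_secondary,
            "n_chain_match": rep.n_chain_match,
            "n_containing": rep.n_containing,
            "n_consensus": rep.n_consensus,
            "n_multi_exon": rep.n_multi_exon,
        }
        logger.info("consensus: %s", summary["consensus"])

    enabled, cfg = _stage_cfg(config, "compare")
    if enabled:
        query = consensus_set if consensus_set is not None else gtf("primary")
        result = _classify.compare_sets(query, gtf("reference"), reverse=True)
        rows = [
            {
                "transcript_id": ct.query.transcript_id,
                "code": ct.code,
                "best_ref_id": ct.best_ref.transcript_id if ct.best_ref else "",
            }
            for ct in result.classified
        ]
        pd.DataFrame(rows).to_csv(outdir / "classified.tsv", sep="\t", index=False)
        summary["compare"] = {
            "counts": result.counts,
            "n_reference": result.n_reference,
            "n_reference_without_overlap": result.n_reference_without_overlap,
        }
        logger.info("compare: %s", result.counts)

    expr = None
    enabled, cfg = _stage_cfg(config, "rpkm")
    if enabled:
        counts = _quantify.read_counts_tsv(inputs["counts"])
        lengths = _quantify.gene_lengths(gtf("reference"))
        expr = _quantify.rpkm_matrix(counts, lengths)
        _quantify.write_expression_tsv(expr, outdir / "rpkm.tsv")
        summary["rpkm"] = {"n_genes": len(expr.genes), "n_samples": len(expr.samples)}

    enabled, cfg = _stage_cfg(config, "enrich")
    if enabled:
        if expr is None:
            counts = _quantify.read_counts_tsv(inputs["counts"])
            expr = _quantify.rpkm_matrix(counts, _quantify.gene_lengths(gtf("reference")))
        ec = _quantify.EnrichmentConfig(
            min_rpkm=float(cfg.get("min_rpkm", 5.0)), fold=float(cfg.get("fold", 10.0))
        )
        pairs = _quantify.enriched_genes(expr, ec)
        pd.DataFrame(pairs, columns=["gene_id", "sample"]).to_csv(
            outdir / "enriched.tsv", sep="\t", index=False
        )
        per_sample = {s: 0 for s in expr.samples}
        for _, s in pairs:
            per_sample[s] += 1
        summary["enrich"] = {"n_enriched": len(pairs), "per_sample": per_sample}
        logger.info("enrich: %d pairs", len(pairs))

    enabled, cfg = _stage_cfg(config, "cluster")
    if enabled:
        if expr is None:
            counts = _quantify.read_counts_tsv(inputs["counts"])
            expr = _quantify.rpkm_matrix(counts, _quantify.gene_lengths(gtf("reference")))
        tree = _cluster.au_support(
            expr,
            n_boot_per_scale=int(cfg.get("n_boot", 1000)),
            seed=seed,
            log2_transform=bool(cfg.get("log2", False)),
        )
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        tree.support_table().to_csv(outdir / "support.tsv", sep="\t", index=False)
        summary["cluster"] = {
            "newick": tree.to_newick(),
            "n_boot_per_scale": int(cfg.get("n_boot", 1000)),
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
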