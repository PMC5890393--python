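"""End-to-end pipeline driver: QC -> normalize -> DE -> quartiles ->
(positional context) -> per-species networks -> cross-species conservation.

Each run writes its artifacts plus a manifest (config, seed, package
version, warning count) to the output directory, so reruns with the same
seed are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import os

import pandas as pd

from . import __version__
from .conservation import (conservation_summary, load_homology, match_modules,
                           overlap_permutation_p, report_conserved)
from .context import classify_all
from .expression import (call_enrichment, de_all_pairs, filter_samples,
                         normalize_median_of_ratios, quartile_bins)
from .io import (ExpressionMatrix, PipelineConfig, annotation_biotypes,
                 read_annotation, read_counts, read_sample_metadata, write_json)
from .network import (build_network, extract_modules, write_edges_tsv,
                      write_graphml, write_node_attributes, write_sif)

logger = logging.getLogger("spongelnc")


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record) -> None:
        self.count += 1


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
        return inner
    return wrap


@_stage("qc_de")
def run_qc_de(config: PipelineConfig, outdir: str) -> None:
    matrix = read_counts(config.counts)
    meta = read_sample_metadata(config.metadata)
    matrix = filter_samples(matrix, meta, config.min_reads)
    matrix = normalize_median_of_ratios(matrix)
    de = de_all_pairs(matrix, meta)
    de.to_csv(os.path.join(outdir, "de_results.tsv"), sep="\t", index=False,
              float_format="%.6g")
    enrich = call_enrichment(de, matrix, meta, config.fdr)
    enrich.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
    quart = quartile_bins(matrix, meta)
    quart.to_csv(os.path.join(outdir, "quartiles.tsv"), sep="\t", index=False)


@_stage("context")
def run_context(annotation_path: str, outdir: str, suffix: str = "") -> None:
    genes = read_annotation(annotation_path)
    lncs = [g for g in genes if g.biotype == "lncRNA"]
    coding = [g for g in genes if g.biotype == "coding"]
    classes = classify_all(lncs, coding)
    out = pd.DataFrame([{"lnc_id": c.lnc_id, "class": c.position_class,
                         "supporting": ",".join(c.supporting)}
                        for c in classes])
    out.to_csv(os.path.join(outdir, f"position_classes{suffix}.tsv"),
               sep="\t", index=False)


@_stage("network")
def run_network(counts_path: str, config: PipelineConfig, outdir: str,
                species: str, de_genes=None):
    matrix = read_counts(counts_path)
    matrix = normalize_median_of_ratios(matrix)
    if de_genes is None:
        de_genes = list(matrix.genes)
    edges = build_network(matrix, de_genes, config.r_pos, config.r_neg,
                          config.edge_p, config.correlation_method)
    biotypes = dict(matrix.biotype)
    prefix = os.path.join(outdir, f"network_{species}")
    write_edges_tsv(edges, prefix + "_edges.tsv")
    write_sif(edges, prefix + ".sif")
    write_graphml(edges, biotypes, prefix + ".graphml")
    write_node_attributes(edges, biotypes, prefix + "_nodes.tsv")
    return extract_modules(edges, biotypes, species=species)


@_stage("conserve")
def run_conserve(modules_a, modules_b, config: PipelineConfig,
                 outdir: str) -> dict:
    homology = load_homology(config.homology, config.evalue)
    matches = match_modules(modules_a, modules_b, homology,
                            config.min_shared_pairs)
    report_conserved(matches, os.path.join(outdir, "conserved_modules.tsv"))
    summary = conservation_summary(matches, modules_a, modules_b)
    if config.n_perm >= 100:
        summary["permutation_p"] = {
            f"{m.module_a}|{m.module_b}": overlap_permutation_p(
                m, modules_a, modules_b, homology,
                n_perm=config.n_perm, seed=config.seed)
            for m in matches}
    write_json(summary, os.path.join(outdir, "conservation_summary.json"))
    return summary


def run_pipeline(config: PipelineConfig) -> int:
    """Run every stage the config provides inputs for; returns exit status."""
    os.makedirs(config.outdir, exist_ok=True)
    counter = _WarningCounter()
    logger.addHandler(counter)
    try:
        if config.counts and config.metadata:
            run_qc_de(config, config.outdir)
        if config.annotation_a:
            run_context(config.annotation_a, config.outdir, "_A")
        if config.annotation_b:
            run_context(config.annotation_b, config.outdir, "_B")
        modules_a = modules_b = None
        if config.counts_dev_a:
            modules_a = run_network(config.counts_dev_a, config,
                                    config.outdir, "A")
        if config.counts_dev_b:
            modules_b = run_network(config.counts_dev_b, config,
                                    config.outdir, "B")
        if config.homology and modules_a is not None and modules_b is not None:
            run_conserve(modules_a, modules_b, config, config.outdir)
    except RuntimeError as exc:
        logger.error(str(exc))
        return 1
    finally:
        logger.removeHandler(counter)
    manifest = {"config": dataclasses.asdict(config), "seed": config.seed,
                "version": __version__, "n_warnings": counter.count}
    write_json(manifest, os.path.join(config.outdir, "manifest.json"))
    return 0
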