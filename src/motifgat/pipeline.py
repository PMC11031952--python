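"""End-to-end pipeline: split → graph → train → evaluate → motifs.

One function, :func:`run_pipeline`, chains every stage with a single
configuration object and a single seed, writes the standard outputs
(metrics TSV, MEME motifs, BED of instances, JSON provenance) when given
an output directory, and returns everything in memory.  Both the CLI's
``all`` subcommand and programmatic use go through it, so a fixed config
and seed reproduce identical reports and motif files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .datasets import DatasetSplit, SequenceRecord, make_split, records_digest
from .evaluate import MetricReport, compute_metrics, write_metrics_tsv
from .gatnet import ModelParameters, TrainConfig, train, predict
from .hetgraph import HeterogeneousGraph, build_graph
from .motifs import (
    MotifModel,
    TFBSInstance,
    build_motifs,
    collect_attention,
    empirical_background,
    find_kmer_seeds,
    merge_overlaps,
    merge_seeds,
    write_bed,
    write_meme,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with the defaults used throughout."""

    lenk: int = 5
    d_k: int = 100
    epochs: int = 300
    learning_rate: float = 0.02
    decay: float = 0.001
    dropout: float = 0.3
    decay_mode: str = "lr_exp"
    sim_max_mismatch: int = 1
    theta_co: float = 0.5
    min_support: int = 5
    pseudocount: float = 0.01
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, learning_rate=self.learning_rate, decay=self.decay,
            dropout=self.dropout, lenk=self.lenk, d_k=self.d_k,
            rng_seed=self.seed, decay_mode=self.decay_mode,
        )


@dataclass
class PipelineResult:
    split: DatasetSplit
    graph: HeterogeneousGraph
    params: ModelParameters
    history: list[dict]
    test_probabilities: np.ndarray
    metrics: MetricReport
    instances: list[TFBSInstance]
    motifs: list[MotifModel]
    counts: dict = field(default_factory=dict)


def run_pipeline(
    records: Sequence[SequenceRecord],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole method on labelled records.

    Stages: stratified 80/10/10 split; heterogeneous graph over the
    training sequences; attention-network training with best-validation
    model selection; test-set metrics; attention collection, seed finding,
    chaining and overlap merging on the training positives; PPM
    construction.  Deterministic for a fixed config (seed included).
    """
    input_hash = records_digest(records)
    split = make_split(records, config.split_fractions, rng_seed=config.seed)
    logger.info("split: %d train / %d val / %d test",
                len(split.train), len(split.validation), len(split.test))
    graph = build_graph(split.train, lenk=config.lenk,
                        sim_max_mismatch=config.sim_max_mismatch)
    params, history = train(graph, config.train_config(), validation=split.validation)

    test_labels = [r.label for r in split.test]
    test_prob = predict(params, graph, split.test)
    metrics = compute_metrics(test_labels, test_prob)
    logger.info("test metrics: acc=%.3f auc=%.3f f1=%.3f",
                metrics.acc, metrics.auc, metrics.f1)

    att = collect_attention(params, graph)
    seeds = find_kmer_seeds(att, graph)
    records_by_id = {r.id: r for r in graph.sequences}
    candidates = merge_seeds(seeds, graph.coexist, records_by_id,
                             lenk=config.lenk, theta_co=config.theta_co)
    instances = merge_overlaps(candidates)
    motifs = build_motifs(instances, min_support=config.min_support,
                          pseudocount=config.pseudocount)
    counts = {
        "n_records": len(records),
        "n_train": len(split.train),
        "n_validation": len(split.validation),
        "n_test": len(split.test),
        "m_kmers": graph.m,
        "n_seeds": len(seeds),
        "n_candidates": len(candidates),
        "n_instances": len(instances),
        "n_motifs": len(motifs),
    }
    logger.info("motif stage: %(n_seeds)d seeds -> %(n_candidates)d candidates -> "
                "%(n_instances)d instances -> %(n_motifs)d motifs", counts)
    result = PipelineResult(
        split=split, graph=graph, params=params, history=history,
        test_probabilities=test_prob, metrics=metrics,
        instances=instances, motifs=motifs, counts=counts,
    )
    if out_dir is not None:
        _write_outputs(result, config, input_hash, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   input_hash: str, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_metrics_tsv(result.metrics, out / "metrics.tsv")
    if result.motifs:
        positives = [r for r in result.graph.sequences if r.label == 1]
        write_meme(result.motifs, out / "motifs.meme",
                   background_freqs=empirical_background(positives))
    if result.instances:
        write_bed(result.instances, out / "tfbs.bed")
    (out / "training_log.json").write_text(json.dumps(result.history))
    provenance = {
        "package": "motifgat",
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "input_sha256": input_hash,
        "counts": result.counts,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
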