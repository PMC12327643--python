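"""End-to-end pipeline runs driven by one YAML config.

A run executes a requested sequence of stages — simulate, featurize,
select, evaluate, null_test, enrich, similarity — writing each stage's
outputs as TSV under an output directory and recording a machine-readable
RunManifest (config snapshot, per-stage seeds, output digests, timings).

One global seed expands deterministically into per-stage seeds as
``stage_seed = (seed * 101 + stage_index) % 2**31``, so stages are
individually reproducible without seed collisions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alphabets import standard_vocabulary
from .evaluation import make_cv_evaluator, stratified_cv
from .enrichment import eligible_records, enrichment_table, summarize_enrichment
from .feature_selection import bootstrap_selection, random_feature_null
from .io import (
    read_domain_annotations,
    read_embedding_table,
    read_fasta,
    attach_domains,
    attach_labels,
    read_labels,
    write_domain_annotations,
    write_fasta,
    write_feature_matrix,
    write_labels,
)
from .representations import build_feature_matrix
from .similarity import ScoringScheme, similarity_study
from .synthetic import GeneratorConfig, generate_classification_dataset, generate_homolog_ladder

logger = logging.getLogger(__name__)

STAGES = ("simulate", "featurize", "select", "evaluate", "null_test", "enrich", "similarity")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    version: str = __version__

    def record_output(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "outputs": self.outputs,
            "timings": self.timings,
            "metrics": self.metrics,
            "version": self.version,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 101 + STAGES.index(stage)) % 2**31


def _validate_config(config: dict) -> list[str]:
    stages = config.get("stages", list(STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) in config: {unknown}")
    feat = config.get("featurize", {})
    if feat.get("method") == "sot" and not feat.get("embeddings"):
        raise ValueError("featurize method 'sot' requires an 'embeddings' path")
    if "simulate" not in stages:
        if not config.get("fasta"):
            raise ValueError("without a simulate stage the config must point to a 'fasta' file")
    return stages


def run_pipeline(config_path: str | Path, outdir: str | Path) -> RunManifest:
    """Execute the stage sequence described by a YAML config file.

    Any stage failure aborts the run with the stage name; the manifest
    (covering the stages that did complete) is written regardless.
    """
    config = yaml.safe_load(Path(config_path).read_text()) or {}
    stages = _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)

    state: dict = {}
    try:
        for stage in stages:
            s = stage_seed(seed, stage)
            manifest.stage_seeds[stage] = s
            t0 = time.perf_counter()
            try:
                _run_stage(stage, config, state, outdir, s, manifest)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            manifest.timings[stage] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.2fs", stage, manifest.timings[stage])
    finally:
        manifest.write(outdir / "manifest.json")
    return manifest


def _run_stage(stage, config, state, outdir: Path, seed: int, manifest: RunManifest) -> None:
    opts = config.get(stage, {}) or {}

    if stage == "simulate":
        gen = GeneratorConfig(**{**opts, "seed": seed})
        records, annotations, truth = generate_classification_dataset(gen)
        state.update(records=records, annotations=annotations, truth=truth)
        write_fasta(records, outdir / "sequences.fasta")
        write_labels({r.id: r.label for r in records}, outdir / "labels.tsv")
        write_domain_annotations(annotations, outdir / "annotations.tsv")
        pd.DataFrame({"trigram": truth}).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for name in ("sequences.fasta", "labels.tsv", "annotations.tsv", "truth.tsv"):
            manifest.record_output(outdir / name)
        return

    if "records" not in state:
        records = read_fasta(config["fasta"])
        if config.get("labels"):
            attach_labels(records, read_labels(config["labels"]))
        if config.get("annotations"):
            attach_domains(records, read_domain_annotations(config["annotations"]))
        state["records"] = records
    records = state["records"]

    if stage == "featurize":
        method = opts.get("method", "hist")
        table = read_embedding_table(opts["embeddings"]) if opts.get("embeddings") else None
        fm = build_feature_matrix(records, method=method, table=table)
        state["features"] = fm
        write_feature_matrix(fm.ids, fm.values, fm.feature_names, outdir / "features.tsv")
        manifest.record_output(outdir / "features.tsv")
        return

    labels = np.array([r.label for r in records])
    fm = state.get("features")

    if stage == "select":
        sel = bootstrap_selection(
            fm.values, labels,
            B=int(opts.get("bootstrap", 50)),
            k=int(opts.get("pool", 2000)),
            m=int(opts.get("top", 200)),
            min_frequency=opts.get("min_frequency"),
            seed=seed,
        )
        state["selection"] = sel
        final = set(sel.final_indices.tolist())
        rows = [
            {
                "feature": f,
                "trigram": fm.feature_names[f],
                "frequency": c,
                "final": int(f in final),
            }
            for f, c in sorted(sel.frequency_ranking.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        pd.DataFrame(rows).to_csv(outdir / "selection.tsv", sep="\t", index=False)
        manifest.record_output(outdir / "selection.tsv")
        if state.get("truth"):
            truth_idx = {fm.feature_names.index(t) for t in state["truth"]}
            recovered = len(truth_idx & final) / len(truth_idx)
            manifest.metrics["signal_recovery"] = recovered
        return

    if stage == "evaluate":
        k = int(opts.get("folds", 10))
        res_full = stratified_cv(fm.values, labels, k=k, seed=seed)
        rows = [{"representation": "full", **_cv_row(res_full)}]
        manifest.metrics["full_cv_auc"] = res_full.mean
        if "selection" in state and state["selection"].n_selected > 0:
            sub = fm.subset(state["selection"].final_indices)
            res_n = stratified_cv(sub.values, labels, k=k, seed=seed)
            rows.append({"representation": f"hist-{sub.n_features}", **_cv_row(res_n)})
            manifest.metrics["histn_cv_auc"] = res_n.mean
        pd.DataFrame(rows).to_csv(outdir / "cv.tsv", sep="\t", index=False)
        manifest.record_output(outdir / "cv.tsv")
        return

    if stage == "null_test":
        if "selection" not in state or state["selection"].n_selected == 0:
            raise ValueError("null_test requires a prior select stage with selected features")
        sel = state["selection"]
        evaluator = make_cv_evaluator(k=int(opts.get("folds", 10)), seed=seed)
        null = random_feature_null(
            fm.values, labels,
            n_features=sel.n_selected,
            evaluator=evaluator,
            observed_indices=sel.final_indices,
            R=int(opts.get("reps", 1000)),
            seed=seed,
        )
        state["null"] = null
        pd.DataFrame({"null_score": null.scores}).to_csv(outdir / "null_scores.tsv", sep="\t", index=False)
        manifest.record_output(outdir / "null_scores.tsv")
        manifest.metrics["null_percentile"] = null.percentile
        manifest.metrics["null_observed_auc"] = null.observed
        from .plotting import plot_null_distribution

        plot_null_distribution(null, outdir / "null_distribution.png")
        return

    if stage == "enrich":
        if "selection" not in state or state["selection"].n_selected == 0:
            raise ValueError("enrich requires a prior select stage with selected features")
        vocab = standard_vocabulary()
        eligible = eligible_records(records)
        table = enrichment_table(state["selection"].final_indices, eligible, vocab)
        rows = [
            {
                "feature": r.feature,
                "trigram": r.trigram,
                "domain_total": r.domain_total,
                "nondomain_total": r.nondomain_total,
                "enriched_in": r.enriched_in,
            }
            for r in table
        ]
        pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        manifest.record_output(outdir / "enrichment.tsv")
        summary = summarize_enrichment(table)
        manifest.metrics.update({k: float(v) for k, v in summary.items()})
        return

    if stage == "similarity":
        parent_length = int(opts.get("parent_length", 150))
        n_per_rate = int(opts.get("n_per_rate", 15))
        rates = tuple(opts.get("mutation_rates", (0.05, 0.15, 0.3, 0.5)))
        _, ladder = generate_homolog_ladder(parent_length, rates, n_per_rate, seed)
        pool = [rec for group in ladder.values() for rec in group]
        vocab = standard_vocabulary()
        from .representations import histogram

        result = similarity_study(
            pool,
            lambda rec: histogram(rec.sequence, vocab),
            n_sets=int(opts.get("n_sets", 3)),
            set_size=int(opts.get("set_size", min(40, len(pool)))),
            scheme=ScoringScheme(),
            seed=seed,
        )
        pd.DataFrame({"set": range(result.n_sets), "rho": result.per_set_rho}).to_csv(
            outdir / "similarity.tsv", sep="\t", index=False
        )
        manifest.record_output(outdir / "similarity.tsv")
        manifest.metrics["similarity_mean_rho"] = result.mean
        return

    raise ValueError(f"unknown stage {stage!r}")


def _cv_row(res) -> dict:
    return {
        "metric": res.metric,
        "mean": res.mean,
        "sd": res.sd,
        "folds": res.k,
        "scores": ",".join(f"{s:.4f}" for s in res.per_fold_scores),
    }
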