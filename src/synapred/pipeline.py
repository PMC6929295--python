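"""End-to-end orchestration: preprocess, train, predict, catalogue, evaluate.

`run_pipeline` chains the stages exactly as the subcommands would:
filter adult-only genes, max-normalize, build the five subsample splits,
train the 15 tuned classifiers, predict genome-wide, cut intersection
catalogues at the configured thresholds, and (when a validation list is
given) trace enrichment-versus-threshold curves.  Every artifact lands in
the output directory alongside a manifest recording versions, the seed and
input hashes, so a rerun with identical config and inputs is reproducible
byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import joblib
import numpy as np

import synapred.io as sio
from synapred.ensemble import exclude_annotated, intersect_at_threshold, predict_all
from synapred.evaluate import enrichment_curve, evaluate_classifier
from synapred.preprocess import filter_adult_only, max_normalize
from synapred.simulate import ConfigurationError
from synapred.training import ALGORITHMS, LabeledGeneSet, train_all

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("synapred")

DEFAULT_CURVE_THRESHOLDS = tuple(np.round(np.arange(0.0, 0.96, 0.05), 2))


@dataclass
class PipelineConfig:
    """Paths and parameters of one full run.  ``seed`` is mandatory."""

    expression_path: Path
    stages_path: Path
    positives_path: Path
    negatives_path: Path
    out_dir: Path
    seed: int
    validation_path: Path | None = None
    annotated_path: Path | None = None
    thresholds: tuple[float, ...] = (0.9, 0.95)
    curve_thresholds: tuple[float, ...] = DEFAULT_CURVE_THRESHOLDS
    k_folds: int = 5
    cv_folds: int = 10
    grids: dict[str, dict[str, list[Any]]] | None = None
    zero_threshold: float = 0.0
    algorithms: tuple[str, ...] = ALGORITHMS

    def __post_init__(self) -> None:
        for name in ("expression_path", "stages_path", "positives_path",
                     "negatives_path", "validation_path", "annotated_path"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.out_dir = Path(self.out_dir)
        if self.seed is None:
            raise ConfigurationError("seed is required: no silent nondeterminism")
        for t in (*self.thresholds, *self.curve_thresholds):
            if not 0.0 <= t <= 1.0:
                raise ConfigurationError(f"threshold {t} outside [0, 1]")
        for name in ("expression_path", "stages_path", "positives_path",
                     "negatives_path", "validation_path", "annotated_path"):
            p = getattr(self, name)
            if p is not None and not p.exists():
                raise ConfigurationError(f"{name} does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator naming the failing stage in any propagated error."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return (and write) the run manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    matrix = _stage("read")(sio.read_expression_tsv)(config.expression_path)
    stages = _stage("read")(sio.read_stage_metadata)(config.stages_path)
    if list(stages["stage"]) != list(matrix.columns):
        raise RuntimeError("pipeline stage 'read' failed: stage metadata does not "
                           "match the expression matrix columns")
    adult_indices = [i for i, a in enumerate(stages["is_adult"]) if a]

    retained, excluded = _stage("preprocess")(filter_adult_only)(
        matrix, adult_indices, zero_threshold=config.zero_threshold)
    normalized = _stage("preprocess")(max_normalize)(retained)
    log.info("preprocess: %d genes in, %d excluded, %d retained",
             matrix.shape[0], len(excluded), normalized.shape[0])
    sio.write_gene_list(excluded, out / "excluded_genes.txt")
    sio.write_expression_tsv(normalized, out / "normalized.tsv")

    pos = set(sio.read_gene_list(config.positives_path))
    neg = set(sio.read_gene_list(config.negatives_path))
    dropped = (pos | neg) - set(normalized.index)
    if dropped:
        log.info("labels: %d labeled genes removed by preprocessing", len(dropped))
    labeled = LabeledGeneSet(frozenset(pos - dropped), frozenset(neg - dropped))

    classifiers, splits = _stage("train")(train_all)(
        labeled, normalized, grids=config.grids, k=config.k_folds,
        cv_folds=config.cv_folds, seed=config.seed, algorithms=config.algorithms)
    log.info("train: %d classifiers from %d splits", len(classifiers), len(splits))

    table = _stage("predict")(predict_all)(
        classifiers, normalized, exclude=labeled.positives | labeled.negatives)
    sio.write_probability_table(table, out / "probabilities.tsv")

    annotated = (set(sio.read_gene_list(config.annotated_path))
                 if config.annotated_path else set())
    catalogue_sizes: dict[str, dict[str, int]] = {}
    for t in config.thresholds:
        cat = _stage("catalogue")(intersect_at_threshold)(table, t)
        sio.write_catalogue(cat.mean_probability, out / f"catalogue_{t:g}.tsv")
        sizes = {"all": len(cat)}
        if annotated:
            novel = exclude_annotated(cat, annotated)
            sio.write_catalogue(novel.mean_probability, out / f"catalogue_{t:g}_novel.tsv")
            sizes["novel"] = len(novel)
        catalogue_sizes[f"{t:g}"] = sizes
        log.info("catalogue at %g: %s", t, sizes)

    split_by_fold = {s.fold_index: s for s in splits}
    metrics = [_stage("evaluate")(evaluate_classifier)(
                   clf, split_by_fold[clf.fold_index], normalized)
               for clf in classifiers]
    metrics_json = {
        "per_classifier": [vars(m) for m in metrics],
        "per_algorithm": {
            alg: {
                stat: float(fn([m.__dict__[stat] for m in metrics if m.algorithm == alg]))
                for stat in ("accuracy", "f1", "auroc")
                for fn in (np.mean,)
            }
            for alg in config.algorithms
        },
    }
    sio.write_json(metrics_json, out / "metrics.json")

    curves = {}
    if config.validation_path:
        validation = set(sio.read_gene_list(config.validation_path)) & set(table.index)
        for grouping in ("all", *config.algorithms):
            curve = _stage("enrich")(enrichment_curve)(
                table, validation, config.curve_thresholds, grouping=grouping)
            frame = curve.to_frame()
            frame.to_csv(out / f"enrichment_curve_{grouping}.tsv", sep="\t",
                         index=False, float_format="%.10g")
            defined = frame[frame["defined"]]
            curves[grouping] = {
                "max_enrichment": (float(defined["enrichment"].max())
                                   if len(defined) else None)
            }

    bundle_path = out / "model_bundle.joblib"
    joblib.dump({"classifiers": classifiers, "splits": splits}, bundle_path)

    from synapred import __version__ as pkg_version

    manifest = {
        "synapred_version": pkg_version,
        "seed": config.seed,
        "inputs": {name: _sha256(p) for name, p in {
            "expression": config.expression_path,
            "stages": config.stages_path,
            "positives": config.positives_path,
            "negatives": config.negatives_path,
            "validation": config.validation_path,
            "annotated": config.annotated_path,
        }.items() if p is not None},
        "n_genes_in": int(matrix.shape[0]),
        "n_excluded": len(excluded),
        "n_labeled": {"positives": len(labeled.positives),
                      "negatives": len(labeled.negatives)},
        "n_splits": len(splits),
        "classifiers": [
            {"algorithm": c.algorithm, "fold_index": c.fold_index,
             "hyperparameters": c.hyperparameters, "cv_score": c.cv_score,
             "seed": c.seed}
            for c in classifiers
        ],
        "catalogue_sizes": catalogue_sizes,
        "enrichment": curves,
    }
    sio.write_json(manifest, out / "manifest.json")
    return manifest
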