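"""Config-driven orchestration of the model grid.

A run expands the cross-product grid (colour space x dictionary size x
quantizer x pooling regime), trains one model per grid point end-to-end on
synthetic (or user-supplied) sub-image datasets, and writes per-model
confusion matrices, a combined report table and a manifest that pins every
seed so a rerun reproduces the outputs byte-identically.

Dataset tags emulate the trap-monitoring design: a ``Lab0d`` set of freshly
trapped catches (decay 0) and a ``Lab7d`` set aged seven days (decay 1).
Pooling regimes: ``none`` trains/tests on Lab0d alone; ``temporal`` merges
both sets; ``categorical`` merges the whitefly pair into BEM-TRI; ``both``
applies the two jointly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .annotations import (
    DEFAULT_TAXONOMY,
    PoolingScheme,
    SubImageRecord,
    split_train_opt,
    apply_pooling,
    whitefly_pooling,
)
from .classifier import SvmHyperParams, train_svm_sgd
from .evaluation import confusion_matrix, precision_recall, render_report
from .features import SiftParams
from .pipeline import BovwPipeline
from .synthetic import generate_dataset
from .vocabulary import build_dictionary

logger = logging.getLogger(__name__)

POOLING_REGIMES = ("none", "temporal", "categorical", "both")


@dataclass(frozen=True)
class ModelConfig:
    """One grid point; every field explicit."""

    model_id: str
    vocsize: int
    colour: str
    quantizer: str
    pooling: str
    seed: int

    def __post_init__(self) -> None:
        if self.pooling not in POOLING_REGIMES:
            raise ValueError(f"unknown pooling regime {self.pooling!r}")


def expand_grid(grid: dict, seed: int = 0) -> list[ModelConfig]:
    """Cross-product of the configured value lists.

    Model ids are free-form descriptive labels built from the grid values.
    """
    colours = list(grid.get("colour", ["greyscale"]))
    vocsizes = list(grid.get("vocsize", [200]))
    quantizers = list(grid.get("quantizer", ["kdtree"]))
    poolings = list(grid.get("pooling", ["temporal"]))
    configs = []
    for pooling in poolings:
        for quantizer in quantizers:
            for vocsize in vocsizes:
                for colour in colours:
                    configs.append(
                        ModelConfig(
                            model_id=f"{colour}-{vocsize}-{quantizer}-{pooling}",
                            vocsize=int(vocsize),
                            colour=colour,
                            quantizer=quantizer,
                            pooling=pooling,
                            seed=seed,
                        )
                    )
    if not configs:
        raise ValueError("no models configured")
    return configs


def _dataset_digest(records: list[SubImageRecord]) -> str:
    h = hashlib.sha256()
    for rec in records:
        h.update(rec.label.encode())
        h.update(rec.dataset_tag.encode())
        h.update(rec.patch.tobytes())
    return h.hexdigest()


def build_synthetic_sets(cfg: dict) -> dict[str, list[SubImageRecord]]:
    """Generate the Lab0d/Lab7d-style train and test record sets."""
    taxonomy = list(cfg.get("taxonomy", DEFAULT_TAXONOMY))
    n_train = int(cfg.get("train_per_class", 100))
    n_test = int(cfg.get("test_per_class", 50))
    seed = int(cfg.get("seed", 0))
    sets = {}
    for tag, decay, counts, offset in [
        ("Lab0d", 0.0, n_train, 1),
        ("Lab7d", 1.0, n_train, 2),
        ("Lab0d-test", 0.0, n_test, 3),
        ("Lab7d-test", 1.0, n_test, 4),
    ]:
        sets[tag] = generate_dataset(
            {c: counts for c in taxonomy},
            decay=decay,
            rng_seed=seed * 10 + offset,
            dataset_tag=tag.replace("-test", ""),
        )
    return sets


def train_model(
    mc: ModelConfig,
    train_records: list[SubImageRecord],
    sift_params: SiftParams | None = None,
    svm: SvmHyperParams | None = None,
    split_fraction: float = 0.75,
    normalization: str = "hellinger",
    descriptor_cache: dict | None = None,
) -> BovwPipeline:
    """Fit dictionary and SVM for one grid point.

    The visual dictionary is built from the model-fitting split only; the
    25% optimization split is held out of clustering and training.  An
    optional ``descriptor_cache`` (keyed by colour space and patch identity)
    avoids recomputing SIFT across grid points.
    """
    sift_params = sift_params or SiftParams()
    svm = svm or SvmHyperParams(seed=mc.seed)
    fit, _opt = split_train_opt(train_records, fraction=split_fraction, rng_seed=mc.seed)
    pipeline = BovwPipeline(
        dictionary=None,  # type: ignore[arg-type]  # set after clustering
        colour_space=mc.colour,
        quantizer=mc.quantizer,
        normalization=normalization,
        sift_params=sift_params,
    )
    descriptor_sets = [
        _cached_descriptors(pipeline, rec, descriptor_cache) for rec in fit
    ]
    pool = np.vstack(
        [ds.descriptors for ds in descriptor_sets if len(ds)]
    )
    dictionary = build_dictionary(
        pool, mc.vocsize, rng_seed=mc.seed, colour_space=mc.colour
    )
    from dataclasses import replace

    pipeline = replace(pipeline, dictionary=dictionary)
    vectors = []
    labels = []
    for rec, ds in zip(fit, descriptor_sets):
        from .vocabulary import encode_bovw

        assignments = pipeline.quantize(ds)
        vectors.append(encode_bovw(assignments, dictionary.vocsize, normalization))
        labels.append(rec.label)
    model = train_svm_sgd(vectors, labels, hyper=svm)
    return pipeline.with_model(model)


def _cache_key(pipeline: BovwPipeline, rec: SubImageRecord) -> tuple:
    return (pipeline.colour_space, rec.dataset_tag, rec.label, rec.source, rec.decay)


def _cached_descriptors(pipeline, rec, cache):
    if cache is None:
        return pipeline.descriptors(rec.patch)
    key = _cache_key(pipeline, rec)
    if key not in cache:
        cache[key] = pipeline.descriptors(rec.patch)
    return cache[key]


def evaluate_model(
    pipeline: BovwPipeline,
    test_records: list[SubImageRecord],
    class_order: tuple[str, ...] | None = None,
    descriptor_cache: dict | None = None,
):
    """Confusion matrix and metrics of a fitted pipeline on test records."""
    true = [rec.label for rec in test_records]
    pred = []
    for rec in test_records:
        ds = _cached_descriptors(pipeline, rec, descriptor_cache)
        from .vocabulary import encode_bovw

        vec = encode_bovw(
            pipeline.quantize(ds), pipeline.dictionary.vocsize, pipeline.normalization
        )
        from .classifier import predict_label

        pred.append(predict_label(pipeline.model, vec).label)
    order = class_order or pipeline.model.classes
    cm = confusion_matrix(true, pred, order)
    return cm, precision_recall(cm)


def _records_for_pooling(sets: dict, pooling: str, train: bool):
    suffix = "" if train else "-test"
    if pooling in ("temporal", "both"):
        records = sets[f"Lab0d{suffix}"] + sets[f"Lab7d{suffix}"]
        scheme_temporal = True
    else:
        records = sets[f"Lab0d{suffix}"]
        scheme_temporal = False
    if pooling in ("categorical", "both"):
        records = apply_pooling(records, whitefly_pooling(temporal=scheme_temporal))
    elif scheme_temporal:
        records = apply_pooling(records, PoolingScheme(temporal=True))
    return records


def run_experiment(config: dict, out_dir) -> dict:
    """Run the full grid; returns {model_id: (ConfusionMatrix, MetricsReport)}.

    Writes per-model confusion matrices, a combined ``report.tsv``, a
    ``manifest.json`` pinning seeds and input digests, and a structured run
    log.  A failing grid point is logged and skipped, not fatal for the run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.get("grid")
    if not grid:
        raise ValueError("no models configured")
    seed = int(config.get("seed", 0))
    models = expand_grid(grid, seed=seed)
    synth_cfg = dict(config.get("synthetic", {}))
    synth_cfg.setdefault("seed", seed)
    sets = build_synthetic_sets(synth_cfg)
    sift_params = SiftParams(**config.get("sift", {}))
    svm = SvmHyperParams(seed=seed, **config.get("svm", {}))
    normalization = config.get("normalization", "hellinger")
    cache: dict = {}
    results = {}
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "grid"} | {"grid": grid},
        "datasets": {
            tag: {"n": len(records), "sha256": _dataset_digest(records)}
            for tag, records in sets.items()
        },
        "models": [],
    }
    log_lines = []
    for mc in models:
        t0 = time.perf_counter()
        try:
            train_records = _records_for_pooling(sets, mc.pooling, train=True)
            test_records = _records_for_pooling(sets, mc.pooling, train=False)
            pipeline = train_model(
                mc,
                train_records,
                sift_params=sift_params,
                svm=svm,
                normalization=normalization,
                descriptor_cache=cache,
            )
            cm, report = evaluate_model(
                pipeline, test_records, descriptor_cache=cache
            )
        except Exception:
            logger.exception("grid point %s failed; skipping", mc.model_id)
            log_lines.append(f"{mc.model_id}\tFAILED")
            continue
        results[mc.model_id] = (cm, report)
        cm.to_frame().to_csv(out / f"confusion_{mc.model_id}.tsv", sep="\t")
        manifest["models"].append(asdict(mc))
        log_lines.append(
            f"{mc.model_id}\tok\t{len(train_records)} train\t"
            f"{len(test_records)} test\t{time.perf_counter() - t0:.1f}s"
        )
    if results:
        by_taxonomy: dict[tuple, dict] = {}
        for model_id, (_cm, rep) in results.items():
            by_taxonomy.setdefault(rep.classes, {})[model_id] = rep
        for i, (_classes, reports) in enumerate(sorted(by_taxonomy.items())):
            name = "report.tsv" if len(by_taxonomy) == 1 else f"report_{i}.tsv"
            render_report(reports, out / name)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return results
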