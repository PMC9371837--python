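"""End-to-end orchestration: features → DE/PSO selection → fusion → PCA → CV.

The pipeline evaluates four arms, mirroring the method's comparison:

- ``original``  — all extracted features
- ``de``        — the DE-selected subset
- ``pso``       — the PSO-selected subset
- ``fused``     — the serial fusion of both subsets, PCA-reduced inside each
  cross-validation training fold (fuse → PCA → classify)

Every artifact embeds the config snapshot and seed that produced it; two runs
with the same config and seed produce identical reports except for the
wall-clock timing fields (``prediction_time``, ``elapsed_seconds``).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path


from . import dataio
from .backbone import BackboneConfig, TrainConfig, build_model, extract_features, finetune
from .classify_eval import ClassifierSpec, crossval_evaluate
from .config import RunConfig
from .dataio import FeatureMatrix
from .fuse_reduce import serial_fuse
from .optimize import DEConfig, FitnessSpec, PSOConfig, SelectionResult, run_selector
from .synthetic import SyntheticFeatureSpec, make_feature_fixture

logger = logging.getLogger(__name__)

TIMING_KEYS = ("prediction_time", "elapsed_seconds")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _subset(fm: FeatureMatrix, mask) -> FeatureMatrix:
    return FeatureMatrix(X=fm.X[:, mask.selected], y=fm.y.copy(),
                         feature_ids=[fm.feature_ids[j] for j in mask.indices])


def _obtain_features(cfg: RunConfig) -> FeatureMatrix:
    inp = cfg.input
    if inp.features:
        return dataio.read_feature_table(inp.features)
    if inp.images:
        images = dataio.load_image_dataset(inp.images, inp.layout, inp.classes)
        images, removed = dataio.filter_blank_images(images, inp.blank_threshold)
        logger.info("blank filter removed %d frame(s)", removed)
        bcfg = BackboneConfig(architecture=cfg.backbone.architecture,
                              feature_layer=cfg.backbone.feature_layer,
                              num_classes=cfg.backbone.num_classes,
                              pretrained=cfg.backbone.pretrained,
                              weights_path=cfg.backbone.weights_path,
                              normalization=cfg.backbone.normalization,
                              init_seed=cfg.stage_seed("backbone"))
        model = build_model(bcfg)
        if cfg.backbone.finetune:
            t = cfg.backbone.train
            model = finetune(model, images, TrainConfig(
                epochs=t.epochs, learning_rate=t.learning_rate,
                batch_size=t.batch_size, momentum=t.momentum,
                seed=cfg.stage_seed("finetune")))
        return extract_features(model, images)
    if inp.synthetic:
        spec = SyntheticFeatureSpec(seed=cfg.stage_seed("synthetic"),
                                    **inp.synthetic.model_dump())
        fm, _ = make_feature_fixture(spec)
        return fm
    raise ValueError("config.input must name features, images, or synthetic")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally persist) a report.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    persisted before the failure are left in place.
    """
    t_start = time.perf_counter()
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def persist(name: str, payload: dict) -> None:
        if outdir:
            (outdir / name).write_text(json.dumps(payload, indent=1))

    report: dict = {"config": cfg.snapshot(), "seed": cfg.seed, "arms": {}}

    try:
        fm = _obtain_features(cfg)
    except Exception as exc:
        raise StageError("input", exc) from exc
    report["n_samples"], report["n_features"] = fm.n, fm.d
    if outdir:
        dataio.write_feature_table(fm, outdir / "features.csv")

    fitness = FitnessSpec(neighbors=cfg.fitness.neighbors,
                          eval_scheme=cfg.fitness.eval_scheme,
                          holdout_fraction=cfg.fitness.holdout_fraction,
                          repeats=cfg.fitness.repeats,
                          folds=cfg.fitness.folds,
                          seed=cfg.stage_seed("fitness"))

    selections: dict[str, SelectionResult] = {}
    for method, section, cls in (("de", cfg.de, DEConfig),
                                 ("pso", cfg.pso, PSOConfig)):
        try:
            mcfg = cls(seed=cfg.stage_seed(method), **section.model_dump())
            selections[method] = run_selector(fm, method, mcfg, fitness)
        except Exception as exc:
            raise StageError(method, exc) from exc
        result = selections[method]
        logger.info("%s selected %d/%d features, best error %.4f",
                    method, result.mask.count, fm.d, result.best_fitness)
        persist(f"{method}_mask.json", result.to_dict())

    try:
        fused = serial_fuse(_subset(fm, selections["de"].mask),
                            _subset(fm, selections["pso"].mask),
                            a_id="de", b_id="pso")
    except Exception as exc:
        raise StageError("fuse", exc) from exc
    if outdir:
        dataio.write_feature_table(fused, outdir / "fused.csv")

    report["selection"] = {
        m: {"count": r.mask.count, "best_fitness": r.best_fitness,
            "trace": r.trace}
        for m, r in selections.items()
    }
    report["fused_width"] = fused.d

    pca_k = min(cfg.pca.k, fused.d)
    arms = {
        "original": (fm, None),
        "de": (_subset(fm, selections["de"].mask), None),
        "pso": (_subset(fm, selections["pso"].mask), None),
        "fused": (fused, pca_k),
    }
    specs = [ClassifierSpec(name=n, seed=cfg.stage_seed("classify"))
             for n in cfg.evaluate.classifiers]
    for arm, (arm_fm, k) in arms.items():
        try:
            ev = crossval_evaluate(arm_fm, specs, folds=cfg.evaluate.folds,
                                   seed=cfg.stage_seed("evaluate"), pca_k=k)
        except Exception as exc:
            raise StageError(f"evaluate:{arm}", exc) from exc
        report["arms"][arm] = {"n_features": arm_fm.d, "pca_k": k,
                               **ev.to_dict()}

    report["elapsed_seconds"] = time.perf_counter() - t_start
    persist("report.json", report)
    return report


def strip_timings(report: dict) -> dict:
    """Copy of a report with hardware-dependent timing fields removed."""
    def scrub(node):
        if isinstance(node, dict):
            return {k: scrub(v) for k, v in node.items() if k not in TIMING_KEYS}
        if isinstance(node, list):
            return [scrub(v) for v in node]
        return node
    return scrub(report)
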