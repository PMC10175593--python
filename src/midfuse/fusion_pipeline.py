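"""Mid-level fusion workflows.

Two study designs are orchestrated here. For authenticity (authentic
FC vs counterfeit) each intelligent-sensor block is screened by PLS-DA
VIP > 1 and the NIR block by CARS; for species (FU/FP/FD/FUS) the
intelligent-sensor blocks are screened by Wilks'-lambda backward
elimination and NIR again by CARS. The selected columns are
concatenated in fixed block order (EN, ET, EE, NIR) and a single
classifier — PLS-DA for authenticity, PCA-DA for species — is fitted
on the fused matrix and evaluated by leave-one-out cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cars as cars_mod
from . import evaluation, pcada, plsda
from .data_model import AUTHENTIC, SOURCES, DataError, FusionDataset

logger = logging.getLogger(__name__)

VIP_REPORT_THRESHOLD = 1.0
LAMBDA_REPORT_THRESHOLD = 0.3


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one fusion run."""

    task: str = "authenticity"
    blocks: tuple[str, ...] = ("EN", "ET", "EE", "NIR")
    pretreatment: str = "center"          # per-block, before selection
    fused_pretreatment: str = "autoscale"  # on the fused matrix
    vip_threshold: float = 1.0
    max_lv: int = 10
    stepwise: pcada.StepwiseConfig = field(default_factory=pcada.StepwiseConfig)
    cars: cars_mod.CarsConfig = field(default_factory=cars_mod.CarsConfig)
    seed: int = 0
    nested: bool = False                  # refit selection inside each LOOCV fold

    def __post_init__(self) -> None:
        if not self.blocks:
            raise DataError("config must include at least one block")
        unknown = [b for b in self.blocks if b not in SOURCES]
        if unknown:
            raise DataError(f"unknown blocks {unknown}")
        if self.vip_threshold < 0:
            raise DataError("vip_threshold must be >= 0")


@dataclass
class SelectionResult:
    """Per-block selected variables with their criterion values."""

    method: dict[str, str]                        # block -> "vip" | "lambda" | "cars"
    indices: dict[str, tuple[int, ...]]
    names: dict[str, tuple[str, ...]]
    criteria: dict[str, pd.DataFrame]             # per-block criterion table
    cars_trace: cars_mod.CarsTrace | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block, idx in self.indices.items():
            for j, name in zip(idx, self.names[block]):
                rows.append({"block": block, "index": j, "variable": name,
                             "method": self.method[block]})
        return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """LOOCV outcome of one fused (or single-block) model."""

    task: str
    blocks: tuple[str, ...]
    confusion: evaluation.ConfusionMatrix
    metrics: evaluation.MetricsReport
    predictions: list[str]
    roc_points: pd.DataFrame | None
    auc: float | None
    explanation: pd.DataFrame
    hyperparameter: int                            # chosen n_lv or n_pc


def _select_block(
    source: str, X: np.ndarray, names, labels, config: PipelineConfig
) -> tuple[tuple[int, ...], pd.DataFrame, str, cars_mod.CarsTrace | None]:
    if source == "NIR":
        cars_cfg = replace(config.cars, seed=config.cars.seed + config.seed)
        trace = cars_mod.cars_select(X, labels, cars_cfg, var_names=names)
        crit = pd.DataFrame({"variable": [names[j] for j in trace.selected],
                             "rmsecv_best": trace.rmsecv[trace.best_run]})
        return trace.selected, crit, "cars", trace
    if config.task == "authenticity":
        n_lv, _ = plsda.select_n_lv(X, labels, config.max_lv,
                                    pretreatment=config.pretreatment)
        model = plsda.fit_plsda(X, labels, n_lv, pretreatment=config.pretreatment)
        vip = plsda.compute_vip(model, threshold=config.vip_threshold)
        selected = vip.selected
        if not selected:
            top = int(np.argmax(vip.scores))
            warnings.warn(f"{source}: no variable above VIP threshold; "
                          f"falling back to top-1 ({names[top]})", UserWarning)
            selected = (top,)
        crit = pd.DataFrame({"variable": list(names), "vip": vip.scores})
        return selected, crit, "vip", None
    # species task: Wilks'-lambda backward elimination
    table, selected = pcada.stepwise_eliminate(X, labels, config.stepwise,
                                               var_names=names)
    crit = pd.DataFrame({"variable": list(names), "wilks_lambda": table.lambdas})
    return selected, crit, "lambda", None


def select_features(dataset: FusionDataset, config: PipelineConfig) -> SelectionResult:
    """Screen each included block by the task's selection rule."""
    ds = dataset.with_blocks(config.blocks)
    labels = list(ds.y)
    result = SelectionResult(method={}, indices={}, names={}, criteria={})
    for source in SOURCES:
        if source not in ds.blocks:
            continue
        block = ds.blocks[source]
        try:
            idx, crit, method, trace = _select_block(
                source, block.values, block.var_names, labels, config)
        except DataError as exc:
            raise DataError(f"feature selection failed for block {source}: {exc}") from exc
        result.indices[source] = tuple(idx)
        result.names[source] = tuple(block.var_names[j] for j in idx)
        result.method[source] = method
        result.criteria[source] = crit
        if trace is not None:
            result.cars_trace = trace
    return result


def fuse_blocks(
    dataset: FusionDataset, selection: SelectionResult
) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate selected columns in block order EN, ET, EE, NIR.

    Returns the fused matrix and a provenance table mapping each fused
    column back to its (block, variable) of origin.
    """
    parts, rows = [], []
    for source in SOURCES:
        if source not in selection.indices or source not in dataset.blocks:
            continue
        block = dataset.blocks[source]
        idx = selection.indices[source]
        bad = [j for j in idx if not 0 <= j < block.n_vars]
        if bad:
            raise DataError(f"selection indices {bad} invalid for block {source}")
        parts.append(block.values[:, list(idx)])
        for j in idx:
            rows.append({"block": source, "index": int(j),
                         "variable": block.var_names[j]})
    if not parts:
        raise DataError("selection covers none of the dataset's blocks")
    fused = np.hstack(parts)
    provenance = pd.DataFrame(rows)
    provenance.insert(0, "fused_column", np.arange(fused.shape[1]))
    return fused, provenance


def _fit_final(fused, labels, config: PipelineConfig):
    """Choose the classifier hyperparameter by LOOCV and fit on all samples."""
    if config.task == "authenticity":
        n_lv, _ = plsda.select_n_lv(fused, labels, config.max_lv,
                                    pretreatment=config.fused_pretreatment)
        model = plsda.fit_plsda(fused, labels, n_lv,
                                pretreatment=config.fused_pretreatment)
        fit = lambda X, y: plsda.fit_plsda(X, y, min(n_lv, X.shape[0] - 2),
                                           pretreatment=config.fused_pretreatment)
        score = lambda m, X: m.predict_scores(X)
        return model, n_lv, fit, score
    model = pcada.fit_pcada(fused, labels, "auto",
                            pretreatment=config.fused_pretreatment,
                            max_pc=config.stepwise.max_pc)
    n_pc = model.n_pc
    fit = lambda X, y: pcada.fit_pcada(X, y, n_pc,
                                       pretreatment=config.fused_pretreatment,
                                       max_pc=config.stepwise.max_pc)
    score = lambda m, X: m.discriminant_scores(X)
    return model, n_pc, fit, score


def _explanation(fused, labels, config, provenance, final_model) -> pd.DataFrame:
    """Per-fused-variable contribution table with the report thresholds."""
    out = provenance.copy()
    if config.task == "authenticity":
        vip = plsda.compute_vip(final_model, threshold=VIP_REPORT_THRESHOLD)
        out["vip"] = vip.scores
        out["influential"] = vip.scores > VIP_REPORT_THRESHOLD
    else:
        lams = np.array([pcada.wilks_lambda(fused[:, j], labels)
                         for j in range(fused.shape[1])])
        out["wilks_lambda"] = lams
        out["influential"] = lams < LAMBDA_REPORT_THRESHOLD
    return out


def run_pipeline(
    dataset: FusionDataset, config: PipelineConfig
) -> tuple[EvaluationReport, object, SelectionResult]:
    """Full workflow: select -> fuse -> tune -> fit -> LOOCV -> explain.

    By default the variable selection is performed once on all samples
    and held fixed inside the LOOCV (the classifier and pretreatment
    are refit per fold); ``config.nested`` refits the selection per
    fold at much higher cost.
    """
    ds = dataset.with_blocks(config.blocks)
    labels = list(ds.y)
    selection = select_features(ds, config)
    fused, provenance = fuse_blocks(ds, selection)
    model, hyper, fit, score_fn = _fit_final(fused, labels, config)

    if config.nested:
        preds, scores = _nested_loocv(ds, config)
    else:
        preds, scores = evaluation.loocv(fused, labels, fit, score_fn=score_fn)

    cm = evaluation.confusion(labels, preds, class_order=model.classes)
    positive = AUTHENTIC if config.task == "authenticity" else None
    rep = evaluation.metrics(cm, positive_class=positive)
    roc_points = auc = None
    if config.task == "authenticity" and scores is not None:
        pos_col = model.classes.index(AUTHENTIC)
        roc_points, auc = evaluation.roc_auc(scores[:, pos_col], labels, AUTHENTIC)

    explanation = _explanation(fused, labels, config, provenance, model)
    report = EvaluationReport(
        task=config.task, blocks=tuple(config.blocks),
        confusion=cm, metrics=rep, predictions=preds,
        roc_points=roc_points, auc=auc,
        explanation=explanation, hyperparameter=hyper,
    )
    return report, model, selection


def _nested_loocv(ds: FusionDataset, config: PipelineConfig):
    """LOOCV refitting selection, fusion and classifier on every fold."""
    labels = list(ds.y)
    ids = list(ds.sample_ids)
    n = len(ids)
    preds, scores = [], []
    for i in range(n):
        train_ids = [s for j, s in enumerate(ids) if j != i]
        sub = FusionDataset(
            blocks={s: b.subset_samples(train_ids) for s, b in ds.blocks.items()},
            labels=ds.labels.subset(train_ids), task=ds.task)
        sel = select_features(sub, config)
        fused_tr, _ = fuse_blocks(sub, sel)
        model, _, fit, score_fn = _fit_final(fused_tr, list(sub.y), config)
        row_parts = [ds.blocks[s].values[i: i + 1, list(sel.indices[s])]
                     for s in SOURCES if s in sel.indices]
        xrow = np.hstack(row_parts)
        preds.append(model.predict(xrow)[0])
        scores.append(np.asarray(score_fn(model, xrow)).ravel())
    return preds, np.vstack(scores)
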