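"""Metrics and the stratified repeated cross-validation harness.

The model is judged the way link-prediction methods on heavily skewed
interaction data are usually judged: balanced positive/negative pair sets,
stratified 10-fold cross-validation repeated with several seeds, and eight
metrics per fold — the six confusion-matrix summaries (accuracy,
specificity, precision, recall, F1, Matthews correlation coefficient) at a
0.5 score threshold, plus the threshold-free AUC-ROC and AUC-PR.  AUC-PR
uses step-wise (non-interpolated) integration of the precision-recall
curve; on balanced test folds the two AUCs are comparable, while on skewed
candidate sets AUC-PR is the more informative number.

A metric whose denominator is zero (possible on tiny folds) is reported as
0 and recorded in the report's ``degenerate`` list rather than raising.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dataio import HeterogeneousDataset, InteractionMatrix
from .features import build_features, sample_balanced_pairs
from .fusion import FusedNetwork, FusionConfig, snf_fuse
from .gip import GipConfig, gip_disease_similarity, gip_drug_similarity
from .model import MlpModel, ModelConfig, TrainingHistory, predict_scores, train_model
from .selection import SelectionConfig, select_views

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "CvConfig",
    "PipelineConfig",
    "CvResult",
    "confusion_metrics",
    "auc_curves",
    "fuse_dataset",
    "run_cross_validation",
    "rank_novel_candidates",
    "compare_reports",
]


@dataclass
class MetricsReport:
    """Confusion counts and the eight evaluation metrics for one scope."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    specificity: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc_roc: float | None = None
    auc_pr: float | None = None
    scope: str = "fold"
    degenerate: list[str] = field(default_factory=list)
    std: dict | None = None  # metric -> sd, for aggregate scope

    def metric(self, name: str) -> float:
        name = name.lower().replace("-", "_")
        if name not in (
            "accuracy", "specificity", "precision", "recall", "f1", "mcc",
            "auc_roc", "auc_pr",
        ):
            raise KeyError(f"unknown metric {name!r}")
        value = getattr(self, name)
        if value is None:
            raise KeyError(f"metric {name!r} not present in this report")
        return value

    def to_dict(self) -> dict:
        out = {
            "scope": self.scope,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "specificity": self.specificity,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "mcc": self.mcc,
            "auc_roc": self.auc_roc, "auc_pr": self.auc_pr,
        }
        if self.degenerate:
            out["degenerate"] = self.degenerate
        if self.std is not None:
            out["std"] = self.std
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class CvConfig:
    """Stratified k-fold protocol: 10 folds, 5 seeded repeats by default."""

    n_folds: int = 10
    n_repeats: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def repeat_seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.n_repeats)]


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, stage by stage."""

    gip: GipConfig = field(default_factory=GipConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    include_gip: bool = True
    strict_no_leakage: bool = False
    # Fused status matrices are row-stochastic (entries ~1/p); min-max
    # rescaling the off-diagonal back to [0, 1] puts the pair features on the
    # similarity scale the He-initialized network expects.
    rescale_fused: bool = True


@dataclass
class CvResult:
    """Aggregate report, per-fold reports and the training histories."""

    aggregate: MetricsReport
    folds: list[MetricsReport]
    histories: list[TrainingHistory]
    selection_reports: dict | None = None


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """The six threshold metrics from raw confusion counts.

    Zero-denominator metrics are reported as 0 and flagged in
    ``report.degenerate``.
    """
    for name, c in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if c < 0:
            raise ValueError(f"negative count {name}={c}")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / total
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    rec = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * prec * rec, prec + rec, "f1")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ratio(float(tp) * tn - float(fp) * fn, mcc_den, "mcc")
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=acc, specificity=spec, precision=prec, recall=rec,
        f1=f1, mcc=mcc, degenerate=degenerate,
    )


def auc_curves(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """(AUC-ROC, AUC-PR); ties rank-averaged, PR integrated step-wise."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUCs")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def _score_fold(labels: np.ndarray, scores: np.ndarray) -> MetricsReport:
    pred = scores >= 0.5
    pos = labels == 1
    report = confusion_metrics(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )
    auc_roc, auc_pr = auc_curves(labels, scores)
    return replace(report, auc_roc=auc_roc, auc_pr=auc_pr)


_AGG_METRICS = (
    "accuracy", "specificity", "precision", "recall", "f1", "mcc",
    "auc_roc", "auc_pr",
)


def _aggregate(folds: list[MetricsReport]) -> MetricsReport:
    """Unweighted mean (and sd) over all fold-level metric values."""
    means = {m: float(np.mean([f.metric(m) for f in folds])) for m in _AGG_METRICS}
    stds = {m: float(np.std([f.metric(m) for f in folds])) for m in _AGG_METRICS}
    return MetricsReport(
        tp=sum(f.tp for f in folds), tn=sum(f.tn for f in folds),
        fp=sum(f.fp for f in folds), fn=sum(f.fn for f in folds),
        accuracy=means["accuracy"], specificity=means["specificity"],
        precision=means["precision"], recall=means["recall"],
        f1=means["f1"], mcc=means["mcc"],
        auc_roc=means["auc_roc"], auc_pr=means["auc_pr"],
        scope="aggregate", std=stds,
    )


def fuse_dataset(
    dataset: HeterogeneousDataset,
    config: PipelineConfig,
    interactions: InteractionMatrix | None = None,
) -> tuple[FusedNetwork, FusedNetwork, dict]:
    """GIP + selection + fusion for both entity types.

    ``interactions`` overrides the matrix used for the GIP views (the strict
    no-leakage mode passes the training-fold matrix here).
    """
    y = interactions if interactions is not None else dataset.interactions
    drug_views = list(dataset.drug_views)
    disease_views = list(dataset.disease_views)
    if config.include_gip:
        drug_views.append(gip_drug_similarity(y, config.gip))
        disease_views.append(gip_disease_similarity(y, config.gip))
    kept_drug, report_drug = select_views(drug_views, config.selection)
    kept_disease, report_disease = select_views(disease_views, config.selection)
    fused_drug = snf_fuse(kept_drug, config.fusion)
    fused_disease = snf_fuse(kept_disease, config.fusion)
    return fused_drug, fused_disease, {"drugs": report_drug, "diseases": report_disease}


def _feature_network(net: FusedNetwork, rescale: bool) -> FusedNetwork:
    if not rescale:
        return net
    sim = net.to_similarity(rescale=True)
    return FusedNetwork(net.entity_ids, sim.values, net.provenance, net.config)


def run_cross_validation(
    dataset: HeterogeneousDataset, config: PipelineConfig | None = None
) -> CvResult:
    """Run the full pipeline under repeated stratified k-fold CV.

    Per repeat seed: draw a balanced pair sample, split it into stratified
    folds (fold label counts differ by at most one within each class), train
    the network on k-1 folds and score the held-out fold.  The aggregate
    report is the unweighted mean over all repeats x folds.

    By default the GIP views are computed once from the full gold standard,
    so fold test labels leak into the features through the GIP profiles.
    With ``strict_no_leakage`` the GIP/selection/fusion stages are recomputed
    inside every training fold with the held-out positives masked out.
    """
    config = config or PipelineConfig()
    y = dataset.interactions
    n_pos = y.n_interactions
    if n_pos < config.cv.n_folds:
        raise ValueError(
            f"{n_pos} positives cannot be split into {config.cv.n_folds} folds"
        )

    fused = None
    selection_reports = None
    if not config.strict_no_leakage:
        fused_drug, fused_disease, selection_reports = fuse_dataset(dataset, config)
        fused_drug = _feature_network(fused_drug, config.rescale_fused)
        fused_disease = _feature_network(fused_disease, config.rescale_fused)
        fused = (fused_drug, fused_disease)

    folds: list[MetricsReport] = []
    histories: list[TrainingHistory] = []
    for repeat, seed in enumerate(config.cv.repeat_seeds):
        pairs = sample_balanced_pairs(y, seed=seed)
        labels = np.array([p[2] for p in pairs], dtype=np.int8)
        splitter = StratifiedKFold(
            n_splits=config.cv.n_folds, shuffle=True, random_state=seed
        )
        if fused is not None:
            table = build_features(fused[0], fused[1], pairs)
        for fold_no, (train_idx, test_idx) in enumerate(
            splitter.split(np.zeros(len(labels)), labels)
        ):
            if fused is None:
                # strict mode: hide the held-out positives from GIP and fusion
                masked = y.values.copy()
                for i in test_idx:
                    if pairs[i][2] == 1:
                        r = y.drug_ids.index(pairs[i][0])
                        c = y.disease_ids.index(pairs[i][1])
                        masked[r, c] = 0
                y_train = InteractionMatrix(y.drug_ids, y.disease_ids, masked)
                f_drug, f_dis, _ = fuse_dataset(dataset, config, interactions=y_train)
                f_drug = _feature_network(f_drug, config.rescale_fused)
                f_dis = _feature_network(f_dis, config.rescale_fused)
                table = build_features(f_drug, f_dis, pairs)
            fold_seed = int(
                np.random.SeedSequence([config.model.seed, seed, fold_no]).generate_state(1)[0]
                % (2**31)
            )
            model_config = replace(config.model, seed=fold_seed)
            model, history = train_model(table.subset(train_idx), model_config)
            scores = predict_scores(model, table.subset(test_idx))
            folds.append(replace(_score_fold(labels[test_idx], scores), scope="fold"))
            histories.append(history)
            logger.info(
                "repeat %d fold %d: AUC-ROC %.3f AUC-PR %.3f",
                repeat, fold_no, folds[-1].auc_roc, folds[-1].auc_pr,
            )
    return CvResult(
        aggregate=_aggregate(folds),
        folds=folds,
        histories=histories,
        selection_reports=selection_reports,
    )


def rank_novel_candidates(
    model: MlpModel,
    fused_drug: FusedNetwork,
    fused_disease: FusedNetwork,
    interactions: InteractionMatrix,
    candidates: list[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.Series]:
    """Score unknown pairs and rank repositioning candidates.

    Candidates must be zero cells of Y (a known positive raises).  Returns
    the candidate table sorted by score descending with a ``predicted``
    column (score > 0.5), plus per-drug counts of predicted novel
    interactions.
    """
    drug_index = {d: i for i, d in enumerate(interactions.drug_ids)}
    disease_index = {d: i for i, d in enumerate(interactions.disease_ids)}
    for drug, disease in candidates:
        if interactions.values[drug_index[drug], disease_index[disease]] == 1:
            raise ValueError(f"candidate ({drug!r}, {disease!r}) is a known interaction")
    if not candidates:
        frame = pd.DataFrame(columns=["drug", "disease", "score", "predicted"])
        return frame, pd.Series(dtype=int, name="n_predicted")
    table = build_features(fused_drug, fused_disease, list(candidates))
    scores = predict_scores(model, table)
    frame = pd.DataFrame(
        {
            "drug": table.drug_ids,
            "disease": table.disease_ids,
            "score": scores,
            "predicted": scores > 0.5,
        }
    ).sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    per_drug = (
        frame[frame["predicted"]].groupby("drug", sort=True).size().rename("n_predicted")
    )
    return frame, per_drug


def compare_reports(
    report_a: MetricsReport, report_b: MetricsReport, metric: str
) -> float:
    """Difference ``100 * (a - b)`` in percentage points, one-decimal rounded."""
    return round(100.0 * (report_a.metric(metric) - report_b.metric(metric)), 1)
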