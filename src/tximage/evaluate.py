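"""Metric suite and the k-fold cross-validation / resolution-sweep harness.

Threshold metrics are computed from the confusion matrix with case = positive
class and control = negative class:

    SEN = TP/(TP+FN)        SPE = TN/(TN+FP)
    PPV = TP/(TP+FP)        NPV = TN/(TN+FN)
    ACC = (TP+TN)/n         F1  = 2*PPV*SEN/(PPV+SEN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AUC-ROC is the trapezoidal area under the ROC curve (equivalently the
Mann-Whitney concordance probability with ties scored 1/2). Ratios with a
zero denominator are reported as NaN with a warning and excluded from fold
aggregation. Fold aggregation reports mean +/- sample standard deviation
(ddof=1) across folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import CNNConfig, build_cnn, compute_class_weights, train_cnn
from .image import apply_normalization, fit_feature_map, normalize_norm2, transform_to_images
from .io import ExpressionMatrix, LabeledDataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVResult",
    "confusion_counts",
    "compute_metrics",
    "auc_roc",
    "crossvalidate",
    "resolution_sweep",
]

log = logging.getLogger(__name__)

METRIC_NAMES = ("auc_roc", "spe", "sen", "npv", "ppv", "acc", "mcc", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise ValueError("confusion counts must describe at least one sample")


@dataclass
class MetricsReport:
    auc_roc: float = math.nan
    spe: float = math.nan
    sen: float = math.nan
    npv: float = math.nan
    ppv: float = math.nan
    acc: float = math.nan
    mcc: float = math.nan
    f1: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(true_labels, predicted_labels) -> ConfusionCounts:
    y = np.asarray(true_labels).astype(int).ravel()
    p = np.asarray(predicted_labels).astype(int).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.size} true vs {p.size} predicted labels")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        FP=int(np.sum((y == 0) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        log.warning("metric %s undefined (zero denominator); reporting NaN", name)
        return math.nan
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All threshold metrics from a confusion matrix (AUC left NaN)."""
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)
    sen = _ratio(tp, tp + fn, "sen")
    spe = _ratio(tn, tn + fp, "spe")
    ppv = _ratio(tp, tp + fp, "ppv")
    npv = _ratio(tn, tn + fn, "npv")
    acc = (tp + tn) / (tp + tn + fp + fn)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc")
    f1 = _ratio(2 * ppv * sen, ppv + sen, "f1") if not (math.isnan(ppv) or math.isnan(sen)) else math.nan
    return MetricsReport(spe=spe, sen=sen, npv=npv, ppv=ppv, acc=acc, mcc=mcc, f1=f1)


def auc_roc(true_labels, probabilities) -> float:
    """Trapezoidal area under the ROC curve."""
    y = np.asarray(true_labels).astype(int).ravel()
    s = np.asarray(probabilities, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return float(np.trapezoid(tpr, fpr))


def evaluate_predictions(true_labels, probabilities, predicted=None) -> MetricsReport:
    """Full report: threshold metrics at the 0.5 rule plus AUC."""
    y = np.asarray(true_labels).astype(int).ravel()
    s = np.asarray(probabilities, dtype=float).ravel()
    p = (s > 0.5).astype(int) if predicted is None else np.asarray(predicted).astype(int)
    rep = compute_metrics(confusion_counts(y, p))
    rep.auc_roc = auc_roc(y, s) if len(np.unique(y)) == 2 else math.nan
    return rep


@dataclass
class CVResult:
    fold_assignments: pd.Series  # sample id -> fold index (1-based)
    per_fold: list[MetricsReport]
    summary: pd.DataFrame  # index metric, columns mean/sd

    @property
    def k(self) -> int:
        return len(self.per_fold)


def _summarize(per_fold: list[MetricsReport]) -> pd.DataFrame:
    tidy = pd.DataFrame([r.as_dict() for r in per_fold])
    return pd.DataFrame({"mean": tidy.mean(skipna=True), "sd": tidy.std(ddof=1, skipna=True)})


def crossvalidate(
    dataset: LabeledDataset,
    *,
    grid_size: int = 50,
    embed_method: str = "tsne",
    perplexity: float = 30.0,
    cnn: CNNConfig | None = None,
    map_scope: str = "train",
    k: int = 12,
    stratified: bool = True,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the image pipeline.

    Per fold: normalize on the training folds, fit the feature map
    (``map_scope="train"``, the default, prevents the held-out fold from
    informing the gene layout; ``"all"`` fits one global map on every
    sample), rasterize, train the CNN with balanced class weights, evaluate
    on the held-out fold. Samples are sorted by id first so fold assignment
    does not depend on input order.
    """
    order = np.argsort(np.asarray(dataset.matrix.sample_ids, dtype=object))
    sample_ids = [dataset.matrix.sample_ids[i] for i in order]
    values = dataset.matrix.values[:, order]
    m = ExpressionMatrix(list(dataset.matrix.gene_ids), sample_ids, values)
    y = dataset.labels.loc[sample_ids].to_numpy()

    if stratified:
        minority = min(np.bincount(y, minlength=2))
        if minority < k:
            raise ValueError(
                f"minority class has {minority} samples < k={k}; use a smaller k"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)

    cnn = cnn or CNNConfig(input_size=grid_size, seed=seed)
    if cnn.input_size != grid_size:
        raise ValueError("cnn.input_size must equal grid_size")

    global_fm = None
    global_norm = None
    if map_scope == "all":
        norm_all, params_all = normalize_norm2(m)
        global_fm = fit_feature_map(
            norm_all, grid_size, method=embed_method, seed=seed,
            perplexity=perplexity, normalization_params=params_all,
        )
        global_norm = params_all
    elif map_scope != "train":
        raise ValueError(f"map_scope must be 'train' or 'all', got {map_scope!r}")

    folds = pd.Series(0, index=pd.Index(sample_ids, name="sample_id"), dtype=int)
    per_fold: list[MetricsReport] = []
    for fold_idx, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y), start=1):
        folds.iloc[te] = fold_idx
        m_tr = ExpressionMatrix(list(m.gene_ids), [sample_ids[i] for i in tr], values[:, tr])
        m_te = ExpressionMatrix(list(m.gene_ids), [sample_ids[i] for i in te], values[:, te])
        if global_fm is None:
            norm_tr, params = normalize_norm2(m_tr)
            fm = fit_feature_map(
                norm_tr, grid_size, method=embed_method, seed=seed,
                perplexity=perplexity, normalization_params=params,
            )
        else:
            fm, params = global_fm, global_norm
            norm_tr = apply_normalization(m_tr, params)
        norm_te = apply_normalization(m_te, params)
        imgs_tr = transform_to_images(norm_tr, fm)
        imgs_te = transform_to_images(norm_te, fm)
        fold_cfg = CNNConfig(**{**cnn.__dict__, "seed": cnn.seed + fold_idx})
        model = build_cnn(fold_cfg)
        clf = train_cnn(model, imgs_tr, y[tr], fold_cfg, compute_class_weights(y[tr]))
        proba = clf.predict_proba(imgs_te)
        per_fold.append(evaluate_predictions(y[te], proba))
        log.info("fold %d/%d: %s", fold_idx, k, {n: round(getattr(per_fold[-1], n), 3) for n in METRIC_NAMES})
    return CVResult(folds, per_fold, _summarize(per_fold))


def resolution_sweep(
    dataset: LabeledDataset,
    resolutions: list[int],
    *,
    k: int = 12,
    seed: int = 0,
    embed_method: str = "tsne",
    perplexity: float = 30.0,
    map_scope: str = "train",
    cnn_template: CNNConfig | None = None,
) -> pd.DataFrame:
    """Cross-validate at each image resolution; tidy summary table.

    Returns one row per (resolution, metric) with mean and sd columns,
    ready for plotting or TSV export.
    """
    rows = []
    for res in resolutions:
        cfg = None
        if cnn_template is not None:
            cfg = CNNConfig(**{**cnn_template.__dict__, "input_size": res})
        cv = crossvalidate(
            dataset, grid_size=res, embed_method=embed_method, perplexity=perplexity,
            cnn=cfg, map_scope=map_scope, k=k, seed=seed,
        )
        for metric, row in cv.summary.iterrows():
            rows.append({"resolution": res, "metric": metric, "mean": row["mean"], "sd": row["sd"]})
    return pd.DataFrame(rows)


def write_metrics(cv: CVResult, out_dir) -> None:
    """Tidy per-fold TSV + summary TSV + JSON twin."""
    from pathlib import Path
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tidy = pd.DataFrame([r.as_dict() for r in cv.per_fold])
    tidy.insert(0, "fold", np.arange(1, len(cv.per_fold) + 1))
    tidy.melt(id_vars="fold", var_name="metric", value_name="value").to_csv(
        out_dir / "metrics_per_fold.tsv", sep="\t", index=False
    )
    cv.summary.rename_axis("metric").to_csv(out_dir / "metrics_summary.tsv", sep="\t")
    (out_dir / "metrics_summary.json").write_text(
        json.dumps({m: {"mean": row["mean"], "sd": row["sd"]} for m, row in cv.summary.iterrows()})
    )
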