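"""Patient-independent evaluation harness.

Leave-one-patient-out (LOSO) cross-validation: each fold trains on every
patient but one and tests on the held-out patient's entire recording —
the patient-independent analog of leave-one-out (segment-level splits
would leak within-recording structure).  Reported rates:

    ACC = (TP+TN)/(TP+TN+FP+FN),  SN = TP/(TP+FN),  SP = TN/(TN+FP)

with zero-denominator rates reported as undefined (``None``), ROC/AUC by
explicit threshold sweep and the trapezoidal rule, fold averages as
mean ± sample standard deviation, plus the ablation suite
(full / no_separation / dann_only / mada_only) and a t-SNE feature export
for visualizing the invariant feature space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import StateError, ValidationError
from .io_segmentation import SegmentBatch
from .training import (
    ModelConfig,
    TrainConfig,
    TrainedModel,
    VARIANTS,
    train_model,
)

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "confusion_from_predictions",
    "compute_metrics",
    "roc_curve_auc",
    "evaluate_on_patient",
    "loso_cross_validation",
    "ablation_suite",
    "tsne_export",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """ACC/SN/SP; a rate with zero denominator is ``None`` (undefined)."""

    acc: float
    sn: float | None
    sp: float | None


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("prediction/label length mismatch")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> Metrics:
    if c.total == 0:
        raise ValidationError("confusion counts are all zero")
    acc = (c.tp + c.tn) / c.total
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return Metrics(acc=acc, sn=sn, sp=sp)


def roc_curve_auc(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC by sweeping thresholds over the unique scores; trapezoidal AUC.

    Returns (curve, auc) with ``curve`` an array of (fpr, tpr) points.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_y = y[order]
    sorted_s = scores[order]
    tp = np.cumsum(sorted_y == 1)
    fp = np.cumsum(sorted_y == 0)
    # keep one operating point per distinct threshold
    distinct = np.r_[np.diff(sorted_s) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# LOSO harness
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-held-out-patient metrics plus fold mean ± sample sd."""

    per_patient: dict[int, dict]
    summary: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, entry in sorted(self.per_patient.items()):
            row = {"patient": pid}
            row.update({k: v for k, v in entry.items() if k != "counts"})
            row.update(dataclasses.asdict(entry["counts"]))
            rows.append(row)
        return pd.DataFrame(rows)


def _summarize(per_patient: dict[int, dict]) -> dict[str, float]:
    out = {}
    for key in ("acc", "sn", "sp", "auc"):
        vals = [e[key] for e in per_patient.values() if e.get(key) is not None]
        if vals:
            out[f"{key}_mean"] = float(np.mean(vals))
            out[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return out


def evaluate_on_patient(trained: TrainedModel, batch: SegmentBatch) -> dict:
    """Confusion counts, rates and AUC on one patient's segments."""
    probs = trained.predict_proba(batch.samples)
    preds = np.argmax(probs, axis=1)
    y = batch.category_labels
    counts = confusion_from_predictions(y, preds)
    metrics = compute_metrics(counts)
    entry = {
        "counts": counts,
        "acc": metrics.acc,
        "sn": metrics.sn,
        "sp": metrics.sp,
    }
    if len(set(y.tolist())) == 2:
        _, auc = roc_curve_auc(probs[:, 1], y)
        entry["auc"] = auc
    else:
        entry["auc"] = None
    return entry


def loso_cross_validation(
    cohort: Sequence[SegmentBatch],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    return_models: bool = False,
):
    """Train/evaluate one fold per patient; never leaks the held-out patient.

    Raises with the fold id attached if a fold's training fails.
    """
    if len(cohort) < 3:
        raise ValidationError("leave-one-patient-out needs at least 3 patients")
    per_patient: dict[int, dict] = {}
    models: dict[int, TrainedModel] = {}
    for fold, held_out in enumerate(cohort):
        train_batches = [b for i, b in enumerate(cohort) if i != fold]
        held_pid = int(held_out.patient_labels[0])
        train_pids = {int(p) for b in train_batches for p in np.unique(b.patient_labels)}
        assert held_pid not in train_pids, "held-out patient leaked into training"
        try:
            trained = train_model(train_batches, config, model_config)
        except Exception as exc:  # annotate with the fold, keep the type
            exc.args = (f"fold {fold} (held-out patient {held_pid}): {exc}",)
            raise
        per_patient[held_pid] = evaluate_on_patient(trained, held_out)
        if return_models:
            models[held_pid] = trained
    report = EvalReport(per_patient=per_patient, summary=_summarize(per_patient))
    return (report, models) if return_models else report


# ---------------------------------------------------------------------------
# Ablations and feature export
# ---------------------------------------------------------------------------


def ablation_suite(
    cohort: Sequence[SegmentBatch],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    variants: Sequence[str] = VARIANTS,
) -> dict[str, EvalReport]:
    """LOSO under identical seeds/folds for each model variant.

    ``no_separation`` drops the disentanglement stage and its losses,
    ``dann_only`` keeps only the global (marginal) adversarial term,
    ``mada_only`` only the per-class (conditional) terms.
    """
    reports = {}
    for variant in variants:
        if variant not in VARIANTS:
            raise ValidationError(f"unknown variant {variant!r}")
        cfg = dataclasses.replace(config, variant=variant)
        reports[variant] = loso_cross_validation(cohort, cfg, model_config)
    return reports


def paired_fold_differences(reports: dict[str, EvalReport], reference: str = "full") -> pd.DataFrame:
    """Per-fold accuracy differences reference − variant."""
    ref = reports[reference].per_patient
    rows = []
    for variant, rep in reports.items():
        if variant == reference:
            continue
        for pid, entry in rep.per_patient.items():
            rows.append(
                {
                    "variant": variant,
                    "patient": pid,
                    "acc_diff": ref[pid]["acc"] - entry["acc"],
                }
            )
    return pd.DataFrame(rows)


def tsne_export(
    trained: TrainedModel,
    batch: SegmentBatch,
    perplexity: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE embedding of the invariant features, one row per segment."""
    if not trained.history:
        raise StateError("model has no training history; train before exporting")
    from sklearn.manifold import TSNE

    feats = trained.invariant_features(batch.samples)
    perplexity = min(perplexity, (len(feats) - 1) / 3.0)
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    ).fit_transform(feats)
    return pd.DataFrame(
        {
            "x": emb[:, 0],
            "y": emb[:, 1],
            "category": batch.category_labels,
            "patient": batch.patient_labels,
        }
    )
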