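"""Performance metrics and cross-validated evaluation.

AUC uses the trapezoidal/rank formulation (equivalent to the Mann-Whitney
U statistic divided by n1*n0, which fixes the tie convention at 0.5 per tied
pair). Precision-recall curves use the step convention. Quantitative tasks
report the Pearson correlation coefficient and the coefficient of
determination R^2 = 1 - SS_res/SS_tot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .dataset import FoldPlan, MultiOmicsDataset, SplitPlan, split_dataset
from .io import ValidationError


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(f"need both classes present, got {classes.tolist()}")
    return (y == classes[1]).astype(int)


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve over unique score thresholds; ties score 0.5."""
    y = _check_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_points(labels, scores) -> pd.DataFrame:
    """(fpr, tpr, threshold) rows of the ROC curve."""
    y = _check_binary(labels)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_curve(labels, scores) -> list[tuple[float, float]]:
    """(recall, precision) points over thresholds, endpoints included,
    ordered by increasing recall."""
    y = _check_binary(labels)
    precision, recall, _ = precision_recall_curve(y, np.asarray(scores, dtype=float))
    pts = sorted(zip(recall.tolist(), precision.tolist()))
    return [(float(r), float(p)) for r, p in pts]


def pcc(y_true, y_pred) -> float:
    """Pearson correlation coefficient."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if len(yt) < 2:
        raise ValidationError("PCC needs at least 2 observations")
    if np.std(yt) == 0:
        raise ValidationError("PCC undefined for constant y_true")
    if np.std(yp) == 0:
        return 0.0
    return float(np.corrcoef(yt, yp)[0, 1])


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("R^2 undefined for constant y_true")
    return 1.0 - float(np.sum((yt - yp) ** 2)) / ss_tot


def positive_scores(d: MultiOmicsDataset, proba: np.ndarray) -> np.ndarray:
    """Positive-class column (last class in sorted order) of probability rows."""
    return proba[:, -1]


def fit_and_score_fold(d: MultiOmicsDataset, train_ids: list[str],
                       test_ids: list[str], model: str = "multicnn",
                       spec=None, params: dict | None = None,
                       seed: int = 0) -> tuple[float, np.ndarray]:
    """Train the requested model on ``train_ids``, score on ``test_ids``.

    Categorical tasks return the test AUC (binary) or accuracy; quantitative
    tasks return the test PCC. The multi-CNN carves a stratified 20%
    validation subset out of the training samples for early stopping.
    """
    d_train = d.subset(train_ids)
    d_test = d.subset(test_ids)
    y_test = d_test.y_codes()

    if model == "multicnn":
        from .multicnn import ModelSpec, build_model, predict, train_model

        spec = spec if spec is not None else ModelSpec(task=d.task)
        plan = split_dataset(d_train, (0.6, 0.2, 0.2), seed=seed)
        fit_ids = plan.train_ids + plan.test_ids  # 80% fit / 20% early-stop val
        m = build_model(spec, d.input_shapes(), seed=seed)
        trained = train_model(m, d_train.subset(fit_ids), d_train.subset(plan.val_ids),
                              spec, seed=seed)
        out = predict(trained, d_test)
        scores = out[:, -1] if d.task == "categorical" else out
    else:
        from .baselines import fit_baseline, flatten, predict_baseline

        flat_train = flatten(d_train)
        flat_test = flatten(d_test)
        fitted = fit_baseline(model, flat_train, params=params, seed=seed)
        out = predict_baseline(fitted, flat_test)
        scores = out[:, -1] if d.task == "categorical" else out

    if d.task == "categorical":
        if len(np.unique(y_test)) < 2:
            raise ValidationError("test fold has a single class")
        return roc_auc(y_test, scores), scores
    return pcc(y_test, scores), scores


@dataclass
class CVReport:
    metric: str
    per_fold: pd.DataFrame  # columns: fold, n_test, value
    mean: float
    sd: float

    def to_csv(self, path) -> None:
        self.per_fold.to_csv(path, index=False)


def evaluate_cv(d: MultiOmicsDataset, folds: FoldPlan, model: str = "multicnn",
                spec=None, params: dict | None = None, seed: int = 0) -> CVReport:
    """Mean and sd of the task metric (AUC or PCC) across the fold plan.

    Folds whose test part contains a single class are skipped with a warning;
    if all folds are skipped an error is raised.
    """
    values, rows = [], []
    for fold in range(folds.k):
        train_ids, test_ids = folds.fold_ids(fold)
        try:
            value, _ = fit_and_score_fold(d, train_ids, test_ids, model=model,
                                          spec=spec, params=params, seed=seed)
        except ValidationError as exc:
            if "single class" in str(exc):
                warnings.warn(f"fold {fold} skipped: {exc}", stacklevel=2)
                continue
            raise
        values.append(value)
        rows.append({"fold": fold, "n_test": len(test_ids), "value": value})
    if not values:
        raise ValidationError("every fold was skipped; no metric computed")
    per_fold = pd.DataFrame(rows)
    metric = "auc" if d.task == "categorical" else "pcc"
    return CVReport(metric, per_fold, float(np.mean(values)),
                    float(np.std(values, ddof=1)) if len(values) > 1 else 0.0)


def holdout_report(d: MultiOmicsDataset, plan: SplitPlan, model: str = "multicnn",
                   spec=None, params: dict | None = None, seed: int = 0) -> dict:
    """Train on the plan's train split, early-stop on val, report on test."""
    value, scores = fit_and_score_fold(
        d, plan.train_ids + plan.val_ids, plan.test_ids,
        model=model, spec=spec, params=params, seed=seed)
    metric = "auc" if d.task == "categorical" else "pcc"
    out = {"metric": metric, "value": value, "n_test": len(plan.test_ids)}
    if d.task == "quantitative":
        y_test = d.subset(plan.test_ids).y_codes()
        out["r_squared"] = r_squared(y_test, scores)
    return out
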