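"""Traditional machine-learning baselines on concatenated multi-omics vectors.

The four comparison models — L2-penalized logistic regression (ridge
regression for quantitative tasks), RBF-kernel SVM, CART decision tree, and
random forest — operate on a flat matrix built by concatenating every layer's
(feature x channel) entries in a fixed layer-then-feature-then-channel order.
Importances come from |coefficients| for linear models, impurity for trees
and forests, and seeded permutation importance for the RBF SVM, whose kernel
admits no per-feature coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .dataset import MultiOmicsDataset
from .io import ValidationError

BASELINE_KINDS = ("lr", "svm", "dt", "rf")


@dataclass
class FlatDataset:
    """Samples x concatenated-features matrix with layer-qualified column names."""

    sample_ids: list[str]
    feature_names: list[str]
    matrix: np.ndarray
    labels: np.ndarray
    task: str
    classes: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValidationError("flat feature names are not unique")
        if self.matrix.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValidationError("flat matrix shape mismatch")


def flatten(d: MultiOmicsDataset) -> FlatDataset:
    """Concatenate all layers into one matrix.

    Column order is layer, then feature, then channel; names are
    ``omicsType:featureID:channelLabel`` so channel-level scores can be
    re-aggregated to features downstream.
    """
    blocks, names = [], []
    for lay in d.layers:
        n, f, c = lay.tensor.shape
        blocks.append(lay.tensor.reshape(n, f * c))
        for feat in lay.feature_ids:
            for ch in lay.channels:
                names.append(f"{lay.omics_type}:{feat}:{ch}")
    classes = d.labels.classes if d.task == "categorical" else None
    return FlatDataset(d.sample_ids, names, np.concatenate(blocks, axis=1),
                       d.y_codes(), d.task, classes)


@dataclass
class TrainedBaseline:
    kind: str
    estimator: object
    feature_names: list[str]
    task: str
    classes: list[str] | None
    seed: int


_DEFAULTS = {
    "lr": {"C": 1.0},
    "svm": {"C": 1.0, "gamma": "scale"},
    "dt": {},
    "rf": {"n_estimators": 500},
}


def fit_baseline(kind: str, d: FlatDataset, params: dict | None = None,
                 seed: int = 0) -> TrainedBaseline:
    """Fit one of the four baselines on the flat matrix."""
    if kind not in BASELINE_KINDS:
        raise ValidationError(f"unknown baseline {kind!r}; choose from {BASELINE_KINDS}")
    if d.task == "categorical" and len(np.unique(d.labels)) < 2:
        raise ValidationError("training labels contain a single class")
    p = {**_DEFAULTS[kind], **(params or {})}
    if d.task == "categorical":
        est = {
            # L2 penalty is sklearn's default for LogisticRegression
            "lr": lambda: LogisticRegression(C=p["C"], max_iter=5000,
                                             random_state=seed),
            "svm": lambda: SVC(kernel="rbf", C=p["C"], gamma=p["gamma"],
                               probability=True, random_state=seed),
            "dt": lambda: DecisionTreeClassifier(random_state=seed, **{
                k: v for k, v in p.items()}),
            "rf": lambda: RandomForestClassifier(random_state=seed, **p),
        }[kind]()
    else:
        est = {
            "lr": lambda: Ridge(alpha=1.0 / p["C"], random_state=seed),
            "svm": lambda: SVR(kernel="rbf", C=p["C"], gamma=p["gamma"]),
            "dt": lambda: DecisionTreeRegressor(random_state=seed, **{
                k: v for k, v in p.items()}),
            "rf": lambda: RandomForestRegressor(random_state=seed, **p),
        }[kind]()
    est.fit(d.matrix, d.labels)
    return TrainedBaseline(kind, est, d.feature_names, d.task, d.classes, seed)


def predict_baseline(model: TrainedBaseline, d: FlatDataset) -> np.ndarray:
    """Positive-class probability rows (categorical) or real values."""
    if d.feature_names != model.feature_names:
        raise ValidationError("flat feature names do not match the fitted baseline")
    if model.task == "categorical":
        return model.estimator.predict_proba(d.matrix)
    return model.estimator.predict(d.matrix)


def baseline_importance(model: TrainedBaseline,
                        d: FlatDataset | None = None,
                        n_repeats: int = 10) -> pd.Series:
    """Per-column importance scores keyed by flat feature names.

    LR: |coefficient|; DT/RF: impurity importance; SVM-RBF: permutation
    importance (``n_repeats`` shuffles, seeded) measured on ``d``.
    """
    est = model.estimator
    if model.kind == "lr":
        coef = est.coef_
        scores = np.abs(coef).sum(axis=0) if coef.ndim == 2 else np.abs(coef)
    elif model.kind in ("dt", "rf"):
        scores = est.feature_importances_
    else:  # svm-rbf: no coefficients exist for a kernelized model
        if d is None:
            raise ValidationError("SVM permutation importance needs a dataset")
        res = permutation_importance(est, d.matrix, d.labels, n_repeats=n_repeats,
                                     random_state=model.seed)
        scores = np.maximum(res.importances_mean, 0.0)
    return pd.Series(scores, index=model.feature_names, name="importance")


def aggregate_to_features(scores: pd.Series) -> pd.DataFrame:
    """Sum channel-level scores back to (layer, feature) rows."""
    parts = scores.index.str.split(":", n=2)
    df = pd.DataFrame({
        "layer": [p[0] for p in parts],
        "feature": [p[1] for p in parts],
        "score": scores.to_numpy(),
    })
    out = df.groupby(["layer", "feature"], sort=False, as_index=False)["score"].sum()
    return out
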