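"""Hyperparameter strategies: defaults, manual overrides, and Bayesian search.

The automated strategy is sequential model-based optimization: a Gaussian-
process surrogate (Matern-5/2 kernel) is fitted to completed trials in a
unit-cube transform of the search space, and each next configuration
maximizes expected improvement over a seeded candidate sample. Failed trials
are recorded with no value and never become the best. With a fixed seed the
trial sequence is replayable trial for trial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .dataset import FoldPlan, MultiOmicsDataset
from .io import OMICS_TYPES, ValidationError


@dataclass(frozen=True)
class Real:
    lo: float
    hi: float
    log: bool = False

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValidationError(f"need lo < hi, got [{self.lo}, {self.hi}]")
        if self.log and self.lo <= 0:
            raise ValidationError("log-uniform dimension needs lo > 0")


@dataclass(frozen=True)
class Integer:
    lo: int
    hi: int

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValidationError(f"need lo < hi, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __post_init__(self):
        if not self.choices:
            raise ValidationError("categorical dimension needs at least one choice")


Dimension = Real | Integer | Categorical


@dataclass
class SearchSpace:
    """Named dimensions over which :func:`tune` searches."""

    dims: dict[str, Dimension]

    def sample(self, rng: np.random.Generator) -> dict:
        cfg = {}
        for name, dim in self.dims.items():
            if isinstance(dim, Real):
                if dim.log:
                    cfg[name] = float(np.exp(rng.uniform(np.log(dim.lo), np.log(dim.hi))))
                else:
                    cfg[name] = float(rng.uniform(dim.lo, dim.hi))
            elif isinstance(dim, Integer):
                cfg[name] = int(rng.integers(dim.lo, dim.hi + 1))
            else:
                cfg[name] = dim.choices[int(rng.integers(len(dim.choices)))]
        return cfg

    def to_unit(self, cfg: dict) -> np.ndarray:
        """Map a configuration into [0, 1]^d for the surrogate."""
        vec = []
        for name, dim in self.dims.items():
            v = cfg[name]
            if isinstance(dim, Real):
                if dim.log:
                    vec.append((math.log(v) - math.log(dim.lo))
                               / (math.log(dim.hi) - math.log(dim.lo)))
                else:
                    vec.append((v - dim.lo) / (dim.hi - dim.lo))
            elif isinstance(dim, Integer):
                vec.append((v - dim.lo) / (dim.hi - dim.lo))
            else:
                n = len(dim.choices)
                vec.append(0.5 if n == 1 else dim.choices.index(v) / (n - 1))
        return np.asarray(vec)

    def validate(self, cfg: dict) -> bool:
        for name, dim in self.dims.items():
            if name not in cfg:
                return False
            v = cfg[name]
            if isinstance(dim, Real) and not dim.lo <= v <= dim.hi:
                return False
            if isinstance(dim, Integer) and not dim.lo <= v <= dim.hi:
                return False
            if isinstance(dim, Categorical) and v not in dim.choices:
                return False
        return True


def space_from_dict(cfg: dict) -> SearchSpace:
    """Build a SearchSpace from a YAML/JSON-style mapping.

    Each entry: ``name: {type: real|int|categorical, lo, hi, log, choices}``.
    """
    dims: dict[str, Dimension] = {}
    for name, d in cfg.items():
        kind = d.get("type", "real")
        if kind == "real":
            dims[name] = Real(float(d["lo"]), float(d["hi"]), bool(d.get("log", False)))
        elif kind in ("int", "integer"):
            dims[name] = Integer(int(d["lo"]), int(d["hi"]))
        elif kind == "categorical":
            dims[name] = Categorical(tuple(d["choices"]))
        else:
            raise ValidationError(f"unknown dimension type {kind!r} for {name!r}")
    if not dims:
        raise ValidationError("search space has no dimensions")
    return SearchSpace(dims)


#: Default search space for the multi-CNN (user-editable via YAML in the CLI).
def default_search_space() -> SearchSpace:
    return SearchSpace({
        "learning_rate": Real(1e-4, 1e-2, log=True),
        "dropout": Real(0.0, 0.5),
        "n_filters_1": Integer(8, 64),
        "n_filters_2": Integer(8, 64),
        "kernel_size": Integer(2, 8),
        "fc_width": Integer(16, 128),
        "batch_size": Categorical((16, 32, 64)),
    })


@dataclass
class TuningResult:
    trials: list[tuple[dict, float | None]]
    best_config: dict
    best_value: float
    seed: int
    space: SearchSpace = field(repr=False, default=None)

    def best_so_far(self) -> list[float]:
        """Monotone non-decreasing best-objective curve over completed trials."""
        curve, best = [], -np.inf
        for _, v in self.trials:
            if v is not None and v > best:
                best = v
            curve.append(best)
        return curve

    def history_frame(self) -> pd.DataFrame:
        rows = []
        for i, (cfg, v) in enumerate(self.trials):
            rows.append({"trial": i, **cfg, "value": v})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.history_frame().to_csv(path, index=False)


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float,
                          xi: float = 0.01) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best - xi) / sigma
    return (mu - best - xi) * norm.cdf(z) + sigma * norm.pdf(z)


def tune(objective, space: SearchSpace, budget: int = 30,
         seed: int = 0, n_init: int | None = None,
         n_candidates: int = 256) -> TuningResult:
    """Maximize ``objective(config)`` over the space within ``budget`` trials.

    The first ``n_init`` trials (default: budget/4, at least 4) are random;
    the rest are proposed by expected improvement under a GP surrogate. A
    trial whose objective raises is marked failed and the search continues;
    if every trial fails an error is raised.
    """
    if budget < 1:
        raise ValidationError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    if n_init is None:
        n_init = max(4, budget // 4)
    trials: list[tuple[dict, float | None]] = []
    X, y = [], []

    for t in range(budget):
        if t < n_init or len(y) < 2:
            cfg = space.sample(rng)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp = GaussianProcessRegressor(
                    kernel=Matern(nu=2.5, length_scale=np.ones(len(space.dims))),
                    alpha=1e-6, normalize_y=True, random_state=0)
                gp.fit(np.asarray(X), np.asarray(y))
            cands = [space.sample(rng) for _ in range(n_candidates)]
            U = np.asarray([space.to_unit(c) for c in cands])
            mu, sigma = gp.predict(U, return_std=True)
            ei = _expected_improvement(mu, sigma, max(y))
            cfg = cands[int(np.argmax(ei))]
        try:
            value = float(objective(cfg))
        except Exception as exc:  # noqa: BLE001 - trial failure is data, not fatal
            warnings.warn(f"trial {t} failed: {exc}", stacklevel=2)
            trials.append((cfg, None))
            continue
        trials.append((cfg, value))
        X.append(space.to_unit(cfg))
        y.append(value)

    if not y:
        raise ValidationError("all tuning trials failed")
    best_idx = int(np.argmax(y))
    done = [(c, v) for c, v in trials if v is not None]
    best_config, best_value = done[best_idx]
    return TuningResult(trials, best_config, float(best_value), seed, space)


def default_config(task: str, omics_types: list[str]):
    """The package's documented default multi-CNN spec for a task/layer combo."""
    from .multicnn import ModelSpec

    if task not in ("categorical", "quantitative"):
        raise ValidationError(f"unknown task {task!r}")
    for t in omics_types:
        if t not in OMICS_TYPES:
            raise ValidationError(f"unknown omics type {t!r}")
    if not 1 <= len(omics_types) <= 3:
        raise ValidationError("need 1-3 omics types")
    return ModelSpec(task=task)


def apply_config(spec, cfg: dict):
    """Return a copy of a ModelSpec with tuned dimensions substituted in."""
    from .multicnn import ModelSpec

    d = spec.to_dict()
    if "learning_rate" in cfg:
        d["learning_rate"] = cfg["learning_rate"]
    if "dropout" in cfg:
        d["dropout"] = cfg["dropout"]
    if "batch_size" in cfg:
        d["batch_size"] = int(cfg["batch_size"])
    if "kernel_size" in cfg or "n_filters_1" in cfg or "n_filters_2" in cfg:
        k = int(cfg.get("kernel_size", d["conv_layers"][0][0]))
        f1 = int(cfg.get("n_filters_1", d["conv_layers"][0][1]))
        f2 = int(cfg.get("n_filters_2", d["conv_layers"][-1][1]))
        d["conv_layers"] = [(k, f1), (k, f2)]
    if "fc_width" in cfg:
        w = int(cfg["fc_width"])
        d["fc_widths"] = [w, max(8, w // 4)]
    return ModelSpec.from_dict(d)


def cv_objective(d: MultiOmicsDataset, config, folds: FoldPlan,
                 model: str = "multicnn", seed: int = 0) -> tuple[float, list[float]]:
    """Mean fold AUC (categorical) or PCC (quantitative) for a configuration.

    Returns the scalar objective and the per-fold values actually used.
    """
    from .evaluation import evaluate_cv
    from .multicnn import ModelSpec

    spec = config if isinstance(config, ModelSpec) or config is None else None
    params = config if isinstance(config, dict) else None
    report = evaluate_cv(d, folds, model=model, spec=spec, params=params, seed=seed)
    return report.mean, report.per_fold["value"].tolist()
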