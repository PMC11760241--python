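"""Bayesian (sequential model-based) hyperparameter search.

A GP surrogate with expected improvement proposes configurations; the
objective is the 3-fold CV AUC of the multi-branch CNN on a small cohort.
"""

import omixnet as ox
from omixnet.tuning import apply_config, cv_objective

spec = ox.SyntheticSpec(
    n_samples=100,
    layers=[ox.LayerSpec("gene_expression", 80, 8, 2.0)],
    seed=1,
)
mats, labels, _ = ox.generate_tables(spec)
dataset = ox.build_dataset(mats, labels, seed=1)
folds = ox.make_cv_folds(dataset, k=3, seed=1)

base = ox.default_config("categorical", ["gene_expression"])
base.max_epochs, base.patience = 10, 4  # keep each trial cheap

space = ox.SearchSpace({
    "learning_rate": ox.Real(1e-4, 1e-2, log=True),
    "dropout": ox.Real(0.0, 0.5),
})


def objective(cfg):
    return cv_objective(dataset, apply_config(base, cfg), folds, seed=1)[0]


result = ox.tune(objective, space, budget=8, seed=0)
print("best CV AUC:", round(result.best_value, 3))
print("best config:", {k: round(v, 5) for k, v in result.best_config.items()})
curve = [round(v, 3) for v in result.best_so_far()]
print("best-so-far curve (monotone):", curve)
# the curve never decreases: each entry is the best objective seen so far
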