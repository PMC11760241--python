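"""Train the multi-branch CNN on a 60/20/20 split and cross-validate it.

The cohort carries a planted signal, so a well-trained model should reach a
high test AUC; the 5-fold CV mean is the headline performance number.
"""

import omixnet as ox

spec = ox.SyntheticSpec(
    n_samples=200,
    layers=[ox.LayerSpec("gene_expression", 300, 10, 2.0),
            ox.LayerSpec("snp", 100, 5, 2.0)],
    seed=7,
)
mats, labels, _ = ox.generate_tables(spec)
dataset = ox.build_dataset(mats, labels, seed=7)

# 60% train / 20% validation (early stopping) / 20% held-out test
plan = ox.split_dataset(dataset, (0.6, 0.2, 0.2), seed=0)
model_spec = ox.ModelSpec(task="categorical", max_epochs=40, patience=10)
graph = ox.build_model(model_spec, dataset.input_shapes(), seed=0)
model = ox.train_model(graph, dataset.subset(plan.train_ids),
                       dataset.subset(plan.val_ids), model_spec, seed=0)
print(f"trained for {len(model.history)} epochs "
      f"(best val loss {min(h['val_loss'] for h in model.history):.3f})")

test = dataset.subset(plan.test_ids)
proba = ox.predict(model, test)  # rows sum to 1: P(neg), P(pos)
auc = ox.roc_auc(test.y_codes(), proba[:, 1])
print(f"held-out test AUC: {auc:.3f}   (1.0 = perfect ranking, 0.5 = chance)")

folds = ox.make_cv_folds(dataset, k=5, seed=0)
report = ox.evaluate_cv(dataset, folds, model="multicnn", spec=model_spec, seed=0)
print(f"5-fold CV mean AUC: {report.mean:.3f} (sd {report.sd:.3f})")
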