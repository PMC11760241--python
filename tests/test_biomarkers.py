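import numpy as np
import pandas as pd
import pytest

import omixnet as ox
from omixnet.biomarkers import report_from_importance
from omixnet.io import ValidationError


class TestSaliencyMap:
    def test_finite_difference_oracle(self, trained_small, small_cohort):
        """Analytic input gradients agree with central differences."""
        model, d, _ = trained_small
        sub = d.subset(d.sample_ids[:5])
        grads = ox.saliency_map(model, sub, target=1)
        from omixnet.multicnn import predict_logits

        rng = np.random.default_rng(0)
        eps = 1e-4
        for _ in range(5):
            n = int(rng.integers(5))
            f = int(rng.integers(sub.layers[0].n_features))
            plus = d.subset(d.sample_ids[:5])
            plus.layers[0].tensor[n, f, 0] += eps
            minus = d.subset(d.sample_ids[:5])
            minus.layers[0].tensor[n, f, 0] -= eps
            fd = (predict_logits(model, plus)[n, 1]
                  - predict_logits(model, minus)[n, 1]) / (2 * eps)
            assert abs(grads[0][n, f, 0] - fd) <= 1e-3

    def test_gradient_shapes_match_layers(self, trio_cohort):
        d, _ = trio_cohort
        spec = ox.ModelSpec(max_epochs=2)
        g = ox.build_model(spec, d.input_shapes(), seed=0)
        plan = ox.split_dataset(d, seed=0)
        model = ox.train_model(g, d.subset(plan.train_ids),
                               d.subset(plan.val_ids), spec, seed=0)
        grads = ox.saliency_map(model, d)
        assert [g.shape for g in grads] == [lay.tensor.shape for lay in d.layers]


class TestAggregateSaliency:
    def test_all_zero_gradients(self):
        out = ox.aggregate_saliency([np.zeros((4, 6, 2))])
        np.testing.assert_array_equal(out[0], 0.0)

    def test_single_hot_feature(self):
        g = np.zeros((3, 5, 2))
        g[:, 2, 1] = 1.0
        out = ox.aggregate_saliency([g])[0]
        np.testing.assert_array_equal(out, [0, 0, 1, 0, 0])

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=(8, 10, 3))
        a = ox.aggregate_saliency([g])[0]
        b = ox.aggregate_saliency([g[::-1]])[0]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestDenseRank:
    def test_spec_example(self):
        ranks = ox.dense_rank({"a": 0.9, "b": 0.7, "c": 0.9, "d": 0.1})
        assert ranks == {"a": 1, "c": 1, "b": 2, "d": 3}

    def test_all_equal_share_rank_one(self):
        assert set(ox.dense_rank({"a": 1.0, "b": 1.0}).values()) == {1}

    def test_singleton(self):
        assert ox.dense_rank({"only": 5.0}) == {"only": 1}

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ox.dense_rank({})

    def test_no_gaps_property(self):
        rng = np.random.default_rng(1)
        values = dict(enumerate(np.round(rng.random(50), 1)))
        ranks = sorted(set(ox.dense_rank(values).values()))
        assert ranks == list(range(1, len(ranks) + 1))


class TestMarkerReport:
    def test_one_entry_per_feature_never_per_channel(self, trio_cohort):
        d, _ = trio_cohort
        spec = ox.ModelSpec(max_epochs=3)
        g = ox.build_model(spec, d.input_shapes(), seed=1)
        plan = ox.split_dataset(d, seed=1)
        model = ox.train_model(g, d.subset(plan.train_ids),
                               d.subset(plan.val_ids), spec, seed=1)
        report = ox.marker_report(model, d)
        assert len(report.table) == 60 + 40 + 30
        assert not report.table["feature"].duplicated().any()

    def test_rank_sorting_consistency(self, trained_small, small_cohort):
        model, d, _ = trained_small
        report = ox.marker_report(model, d)
        t = report.table
        assert t["saliency"].is_monotonic_decreasing
        assert t["dense_rank"].is_monotonic_increasing
        assert t["dense_rank"].iloc[0] == 1
        ranks = sorted(t["dense_rank"].unique())
        assert ranks == list(range(1, len(ranks) + 1))


class TestTopMarkers:
    def _report(self, values):
        table = pd.DataFrame({
            "feature": [f"f{i}" for i in range(len(values))],
            "layer": "gene_expression",
            "saliency": values,
        })
        table["dense_rank"] = table["saliency"].rank(
            method="dense", ascending=False).astype(int)
        table = table.sort_values("saliency", ascending=False).reset_index(drop=True)
        return ox.MarkerReport(table, "test", 1)

    def test_top_k_with_boundary_ties(self):
        rep = self._report([0.9, 0.5, 0.5, 0.5, 0.1])
        top = ox.top_markers(rep, k=2)
        assert len(top) == 4  # the three tied 0.5s all enter

    def test_threshold_above_max_is_empty(self):
        rep = self._report([0.3, 0.2])
        assert len(ox.top_markers(rep, threshold=0.5)) == 0

    def test_k_one_is_argmax(self):
        rep = self._report([0.3, 0.9, 0.2])
        top = ox.top_markers(rep, k=1)
        assert top["feature"].tolist() == ["f1"]

    def test_k_beyond_total_warns_and_returns_all(self):
        rep = self._report([0.3, 0.2])
        with pytest.warns(UserWarning, match="returning all"):
            top = ox.top_markers(rep, k=10)
        assert len(top) == 2

    def test_exactly_one_selector_required(self):
        rep = self._report([0.3])
        with pytest.raises(ValidationError):
            ox.top_markers(rep)
        with pytest.raises(ValidationError):
            ox.top_markers(rep, k=1, threshold=0.1)


class TestMapMarkersToGenes:
    def _markers(self):
        return pd.DataFrame({
            "feature": ["cg001", "cg002", "TP53", "cg404"],
            "layer": ["dna_methylation", "dna_methylation",
                      "gene_expression", "dna_methylation"],
            "saliency": [0.9, 0.8, 0.7, 0.6],
            "dense_rank": [1, 2, 3, 4],
        })

    def test_annotated_markers_replaced(self):
        ann = ox.MarkerAnnotation({"cg001": ("chr1", 0, 10, "GENE1"),
                                   "cg002": ("chr1", 20, 30, "GENE2")})
        mapped, unmapped = ox.map_markers_to_genes(self._markers(), ann)
        assert set(mapped["gene"]) == {"GENE1", "GENE2", "TP53"}
        assert unmapped == ["cg404"]

    def test_gene_typed_markers_pass_through(self):
        mapped, unmapped = ox.map_markers_to_genes(self._markers(),
                                                   ox.MarkerAnnotation({}))
        assert mapped["gene"].tolist() == ["TP53"]
        assert set(unmapped) == {"cg001", "cg002", "cg404"}

    def test_duplicate_gene_keeps_best_rank(self):
        ann = ox.MarkerAnnotation({"cg001": ("chr1", 0, 10, "GENE1"),
                                   "cg002": ("chr1", 20, 30, "GENE1")})
        mapped, _ = ox.map_markers_to_genes(self._markers(), ann)
        row = mapped[mapped["gene"] == "GENE1"]
        assert len(row) == 1
        assert row["dense_rank"].iloc[0] == 1


def test_baseline_importance_report_pipeline(small_cohort):
    """Baseline |coefficients| flow into the same dense-rank report format."""
    d, manifest = small_cohort
    flat = ox.flatten(d)
    fitted = ox.fit_baseline("lr", flat, seed=0)
    scores = ox.baseline_importance(fitted)
    from omixnet.baselines import aggregate_to_features

    report = report_from_importance(aggregate_to_features(scores), "lr", d.n_samples)
    check = ox.manifest_check(report, manifest, k=10)
    assert check["precision_at_k"] >= 0.8  # LR recovers the planted markers
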