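import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omixnet as ox
from omixnet.io import ValidationError


class TestGenerate:
    def test_planted_mean_shift_within_three_se(self):
        """Empirical class-mean difference of planted features ~ effect size."""
        spec = ox.SyntheticSpec(200, [ox.LayerSpec("gene_expression", 1000, 10, 2.0)],
                                seed=7)
        mats, labels, manifest = ox.generate_tables(spec)
        m = next(iter(mats.values()))
        y = np.asarray(labels.values) == "pos"
        n1, n0 = y.sum(), (~y).sum()
        se = np.sqrt(1 / n1 + 1 / n0)
        planted = manifest.planted[next(iter(manifest.planted))]
        diffs = []
        for feat in planted:
            col = m.values[feat].to_numpy()
            diffs.append(col[y].mean() - col[~y].mean())
        # each feature within a generous individual band, the planted-set
        # average within 3 standard errors of its own (tighter) sampling sd
        assert max(abs(d - 2.0) for d in diffs) < 4.5 * se
        assert abs(np.mean(diffs) - 2.0) < 3 * se / np.sqrt(len(planted))

    def test_snp_planted_features_shift_category_frequency(self):
        spec = ox.SyntheticSpec(600, [ox.LayerSpec("snp", 50, 5, 2.0)], seed=3)
        mats, labels, manifest = ox.generate_tables(spec)
        m = next(iter(mats.values()))
        y = np.asarray(labels.values) == "pos"
        planted = manifest.planted[next(iter(manifest.planted))]
        shifts = []
        for feat in m.feature_ids:
            col = m.values[feat].to_numpy()
            freq_pos = pd.Series(col[y]).value_counts(normalize=True)
            freq_neg = pd.Series(col[~y]).value_counts(normalize=True)
            tv = 0.5 * (freq_pos.subtract(freq_neg, fill_value=0).abs().sum())
            shifts.append((feat, tv))
        tv_map = dict(shifts)
        planted_mean = np.mean([tv_map[f] for f in planted])
        null_mean = np.mean([tv for f, tv in shifts if f not in planted])
        assert planted_mean > null_mean + 0.1

    def test_same_seed_byte_identical_files(self, tmp_path):
        spec = ox.SyntheticSpec(30, [ox.LayerSpec("gene_expression", 10, 2),
                                     ox.LayerSpec("snp", 8, 2)], seed=5)
        a = ox.generate(spec, tmp_path / "a")
        b = ox.generate(spec, tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_generated_files_round_trip_through_readers(self, tmp_path):
        spec = ox.SyntheticSpec(20, [ox.LayerSpec("gene_expression", 6, 1,
                                                  missing_rate=0.1),
                                     ox.LayerSpec("cnv", 5, 1)], seed=9)
        paths = ox.generate(spec, tmp_path)
        ge = ox.read_omics_csv(paths["layer0_gene_expression"], "gene_expression")
        cnv = ox.read_omics_csv(paths["layer1_cnv"], "cnv")
        labels = ox.read_labels(paths["labels"], "categorical")
        d = ox.build_dataset({"ge": ge, "cnv": cnv}, labels, seed=9)
        assert d.n_samples == 20
        manifest = ox.Manifest.from_json(paths["manifest"])
        assert set(manifest.planted) == {"layer0_gene_expression", "layer1_cnv"}

    def test_no_planted_markers_gives_chance_auc(self):
        aucs = []
        for seed in range(3):
            spec = ox.SyntheticSpec(100, [ox.LayerSpec("gene_expression", 40, 0)],
                                    seed=seed)
            mats, labels, manifest = ox.generate_tables(spec)
            assert manifest.all_planted() == set()
            d = ox.build_dataset(mats, labels, seed=seed)
            folds = ox.make_cv_folds(d, k=3, seed=seed)
            aucs.append(ox.evaluate_cv(d, folds, model="lr", seed=seed).mean)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_null_features_look_standard_normal(self):
        """>=95% of null features pass a normality check at alpha=0.01."""
        spec = ox.SyntheticSpec(150, [ox.LayerSpec("gene_expression", 200, 0)],
                                seed=13)
        mats, _, _ = ox.generate_tables(spec)
        x = next(iter(mats.values())).values.to_numpy()
        pvals = [stats.normaltest(x[:, j]).pvalue for j in range(x.shape[1])]
        assert np.mean(np.asarray(pvals) > 0.01) >= 0.95

    def test_missing_rate_applied(self):
        spec = ox.SyntheticSpec(100, [ox.LayerSpec("gene_expression", 50, 0,
                                                   missing_rate=0.2)], seed=2)
        mats, _, _ = ox.generate_tables(spec)
        frac = next(iter(mats.values())).values.isna().to_numpy().mean()
        assert 0.15 < frac < 0.25

    def test_infeasible_frequency_shift_rejected(self):
        with pytest.raises(ValidationError, match="frequency shift"):
            ox.generate_tables(ox.SyntheticSpec(
                10, [ox.LayerSpec("snp", 5, 2, effect=7.0)], seed=0))

    def test_quantitative_labels_track_planted_signal(self):
        spec = ox.SyntheticSpec(150, [ox.LayerSpec("gene_expression", 50, 10, 3.0)],
                                task="quantitative", seed=4)
        mats, labels, manifest = ox.generate_tables(spec)
        m = next(iter(mats.values()))
        planted = list(manifest.all_planted())
        signal = m.values[planted].mean(axis=1).to_numpy()
        assert ox.pcc(np.asarray(labels.values, dtype=float), signal) > 0.5


class TestManifestCheck:
    def _report(self, features, planted_first=0):
        table = pd.DataFrame({
            "feature": features,
            "layer": "gene_expression",
            "saliency": np.linspace(1, 0.1, len(features)),
        })
        table["dense_rank"] = np.arange(1, len(features) + 1)
        return ox.MarkerReport(table, "toy", 10)

    def test_perfect_recovery(self):
        manifest = ox.Manifest({}, {"L": ["f0", "f1"]})
        report = self._report(["f0", "f1", "f2", "f3"])
        out = ox.manifest_check(report, manifest, k=2)
        assert out["precision_at_k"] == 1.0
        assert out["recall_at_k"] == 1.0

    def test_k_zero_rejected(self):
        manifest = ox.Manifest({}, {"L": ["f0"]})
        with pytest.raises(ValidationError):
            ox.manifest_check(self._report(["f0"]), manifest, k=0)

    def test_disjoint_namespaces_rejected(self):
        manifest = ox.Manifest({}, {"L": ["other0"]})
        with pytest.raises(ValidationError, match="share no feature"):
            ox.manifest_check(self._report(["f0", "f1"]), manifest, k=1)

    def test_random_report_matches_permutation_expectation(self):
        """Random rankings of 1000 features with 10 planted: precision@10
        averages 10/1000 = 0.01 over shuffles."""
        rng = np.random.default_rng(0)
        features = [f"f{i}" for i in range(1000)]
        manifest = ox.Manifest({}, {"L": features[:10]})
        precisions = []
        for _ in range(100):
            order = rng.permutation(features).tolist()
            precisions.append(
                ox.manifest_check(self._report(order), manifest, k=10)["precision_at_k"])
        assert abs(np.mean(precisions) - 0.01) <= 0.02
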