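import numpy as np
import pytest

import omixnet as ox
from omixnet.io import ValidationError
from omixnet.tuning import apply_config


QUADRATIC_SPACE = ox.SearchSpace({"x": ox.Real(0.0, 1.0)})


def quadratic(cfg):
    return -((cfg["x"] - 0.3) ** 2)


class TestTune:
    def test_quadratic_optimum_found(self):
        """Grid search at step 0.01 puts the optimum at x=0.3; budget-30
        Bayesian search must land within 0.1 of it."""
        grid_best = max((round(x, 2) for x in np.arange(0, 1.001, 0.01)),
                        key=lambda x: quadratic({"x": x}))
        assert grid_best == pytest.approx(0.3)
        result = ox.tune(quadratic, QUADRATIC_SPACE, budget=30, seed=0)
        assert abs(result.best_config["x"] - 0.3) < 0.1

    def test_budget_one_returns_single_trial(self):
        result = ox.tune(quadratic, QUADRATIC_SPACE, budget=1, seed=0)
        assert len(result.trials) == 1
        assert result.best_config == result.trials[0][0]

    def test_seeded_replay_identical(self):
        a = ox.tune(quadratic, QUADRATIC_SPACE, budget=15, seed=42)
        b = ox.tune(quadratic, QUADRATIC_SPACE, budget=15, seed=42)
        assert a.trials == b.trials
        assert a.best_config == b.best_config

    def test_best_so_far_monotone(self):
        result = ox.tune(quadratic, QUADRATIC_SPACE, budget=25, seed=1)
        curve = result.best_so_far()
        assert all(b >= a for a, b in zip(curve, curve[1:]))
        assert curve[-1] == result.best_value

    def test_failed_trials_skipped_not_fatal(self):
        calls = {"n": 0}

        def flaky(cfg):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return quadratic(cfg)

        with pytest.warns(UserWarning, match="failed"):
            result = ox.tune(flaky, QUADRATIC_SPACE, budget=12, seed=2)
        assert sum(v is None for _, v in result.trials) == 4
        assert result.best_value == max(v for _, v in result.trials if v is not None)

    def test_all_failed_raises(self):
        def broken(cfg):
            raise RuntimeError("no")

        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError, match="all tuning trials failed"):
                ox.tune(broken, QUADRATIC_SPACE, budget=3, seed=0)

    def test_bayesian_beats_random_search_median(self):
        """Over 20 replicate seeds, budget-30 model-based search attains at
        least the median objective of 30-trial pure random search."""
        seeds = range(20)
        random_best = []
        for s in seeds:
            rng = np.random.default_rng(s + 1000)
            random_best.append(max(quadratic(QUADRATIC_SPACE.sample(rng))
                                   for _ in range(30)))
        med = np.median(random_best)
        bo_best = [ox.tune(quadratic, QUADRATIC_SPACE, budget=30, seed=s).best_value
                   for s in seeds]
        assert np.median(bo_best) >= med

    def test_mixed_space_types(self):
        space = ox.SearchSpace({
            "lr": ox.Real(1e-4, 1e-1, log=True),
            "width": ox.Integer(4, 64),
            "batch": ox.Categorical((16, 32, 64)),
        })

        def objective(cfg):
            return -abs(np.log10(cfg["lr"]) + 2) - abs(cfg["width"] - 32) / 64

        result = ox.tune(objective, space, budget=25, seed=3)
        assert space.validate(result.best_config)
        assert 1e-4 <= result.best_config["lr"] <= 1e-1


class TestDefaultConfig:
    def test_lookup_returns_default_spec(self):
        spec = ox.default_config("categorical", ["gene_expression"])
        assert spec.task == "categorical"
        assert spec.conv_layers == [(4, 16), (4, 32)]
        assert spec.fc_widths == [64, 16]
        assert spec.dropout == 0.25

    def test_unknown_omics_rejected(self):
        with pytest.raises(ValidationError, match="unknown omics type"):
            ox.default_config("categorical", ["lipidomics"])

    def test_defaults_within_search_space_bounds(self):
        spec = ox.default_config("categorical", ["snp"])
        space = ox.default_search_space()
        cfg = {
            "learning_rate": spec.learning_rate,
            "dropout": spec.dropout,
            "n_filters_1": spec.conv_layers[0][1],
            "n_filters_2": spec.conv_layers[1][1],
            "kernel_size": spec.conv_layers[0][0],
            "fc_width": spec.fc_widths[0],
            "batch_size": spec.batch_size,
        }
        assert space.validate(cfg)

    def test_apply_config_substitutes_dimensions(self):
        spec = ox.default_config("categorical", ["snp"])
        new = apply_config(spec, {"learning_rate": 5e-3, "kernel_size": 6,
                                  "n_filters_1": 12, "fc_width": 48})
        assert new.learning_rate == 5e-3
        assert new.conv_layers[0] == (6, 12)
        assert new.fc_widths[0] == 48
        assert new.dropout == spec.dropout  # untouched dimensions preserved


class TestSpaceFromDict:
    def test_yaml_style_mapping_builds_space(self):
        from omixnet.tuning import space_from_dict

        space = space_from_dict({
            "learning_rate": {"type": "real", "lo": 1e-4, "hi": 1e-2, "log": True},
            "width": {"type": "int", "lo": 8, "hi": 64},
            "batch": {"type": "categorical", "choices": [16, 32, 64]},
        })
        rng = np.random.default_rng(0)
        cfg = space.sample(rng)
        assert space.validate(cfg)
        assert isinstance(cfg["width"], int)

    def test_unknown_type_rejected(self):
        from omixnet.tuning import space_from_dict

        with pytest.raises(ValidationError, match="unknown dimension type"):
            space_from_dict({"x": {"type": "boolean"}})


class TestSearchSpaceValidation:
    def test_bad_bounds_rejected(self):
        with pytest.raises(ValidationError):
            ox.Real(1.0, 0.5)
        with pytest.raises(ValidationError):
            ox.Integer(5, 5)
        with pytest.raises(ValidationError):
            ox.Categorical(())

    def test_log_dimension_samples_within_bounds(self):
        space = ox.SearchSpace({"lr": ox.Real(1e-5, 1e-1, log=True)})
        rng = np.random.default_rng(0)
        draws = [space.sample(rng)["lr"] for _ in range(200)]
        assert all(1e-5 <= v <= 1e-1 for v in draws)
        # log-uniform: about half the draws below the geometric midpoint
        below = sum(v < 1e-3 for v in draws)
        assert 60 <= below <= 140
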