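"""MLP training with RPROP, analyzer rules and whole-image classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcica.classifier import (ANALYZER_PRESETS, UNCLASSIFIED, AnalyzerRule,
                              MLPModel, RpropConfig, analyze, analyze_batch,
                              classify_image, sweep_train, train_mlp)
from mcica.errors import ConfigError, ValidationError
from mcica.phantom import LABEL_BACKGROUND, LABEL_CLUSTERED, LABEL_ISOLATED


def _separable_dataset(seed=0, n=300):
    """Two well-separated Gaussian blobs in 2-D."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-2.0, 0.3, (n, 2)), rng.normal(2.0, 0.3, (n, 2))])
    y = np.repeat([0, 1], n)
    idx = rng.permutation(2 * n)
    X, y = X[idx], y[idx]
    split = {"learn": np.arange(0, int(1.5 * n)),
             "val": np.arange(int(1.5 * n), 2 * n)}
    return X, y, split


class TestAnalyze:
    @pytest.mark.parametrize("outputs,preset,expected", [
        ((0.9, 0.1), "402040", 0),
        ((0.6, 0.5), "402040", UNCLASSIFIED),   # runner-up exceeds l
        ((0.5, 0.4), "402040", UNCLASSIFIED),   # winner below h
        ((0.1, 0.9, 0.2), "402040", 1),
        ((0.4, 0.3), "wta0", 0),
        ((0.4, 0.3), "wta1", UNCLASSIFIED),
        ((0.56, 0.1), "wta2", 0),
        ((0.56, 0.1), "wta3", UNCLASSIFIED),
    ])
    def test_preset_decisions(self, outputs, preset, expected):
        decision = analyze(outputs, ANALYZER_PRESETS[preset])
        assert decision.label == expected
        assert decision.winning_output == pytest.approx(max(outputs))

    def test_wta_tie_is_unclassified(self):
        assert analyze((0.7, 0.7), ANALYZER_PRESETS["wta0"]).label == UNCLASSIFIED

    def test_invalid_rule_configs_rejected(self):
        with pytest.raises(ConfigError):
            AnalyzerRule("rule402040", h=0.4, l=0.5)
        with pytest.raises(ConfigError):
            AnalyzerRule("wta", h=1.5)
        with pytest.raises(ConfigError):
            AnalyzerRule("softmax", h=0.5)

    def test_outputs_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            analyze((1.2, 0.1), ANALYZER_PRESETS["wta0"])

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=6),
           st.integers(1, 5))
    @settings(max_examples=100, derandomize=True)
    def test_lowering_nonwinning_output_never_flips_402040_acceptance(
            self, outputs, which):
        rule = ANALYZER_PRESETS["402040"]
        out = np.asarray(outputs)
        before = analyze_batch(out[None, :], rule)[0]
        j = which % len(out)
        if j == int(np.argmax(out)):
            return
        lowered = out.copy()
        lowered[j] = min(lowered[j], rule.l / 2)
        after = analyze_batch(lowered[None, :], rule)[0]
        if before != UNCLASSIFIED:
            assert after == before

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5))
    @settings(max_examples=100, derandomize=True)
    def test_wta0_with_unique_max_never_unclassified(self, outputs):
        out = np.asarray(outputs)
        if (out == out.max()).sum() != 1 or out.max() == 0.0:
            return
        assert analyze_batch(out[None, :], ANALYZER_PRESETS["wta0"])[0] \
            == int(np.argmax(out))


class TestTrainMlp:
    def test_separable_data_reaches_high_validation_score(self):
        X, y, split = _separable_dataset()
        model = train_mlp(X, y, split, n_hidden=50,
                          config=RpropConfig(max_epochs=200), seed=0)
        assert model.validation_score >= 0.95

    def test_zero_epochs_returns_initial_model(self):
        X, y, split = _separable_dataset()
        cfg = RpropConfig(max_epochs=0)
        a = train_mlp(X, y, split, 50, cfg, seed=1)
        b = train_mlp(X, y, split, 50, cfg, seed=1)
        assert a.epochs_run == 0
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)

    def test_same_seed_gives_identical_weights(self):
        X, y, split = _separable_dataset()
        cfg = RpropConfig(max_epochs=50)
        a = train_mlp(X, y, split, 60, cfg, seed=3)
        b = train_mlp(X, y, split, 60, cfg, seed=3)
        for pa, pb in zip((a.W1, a.b1, a.W2, a.b2), (b.W1, b.b1, b.W2, b.b2)):
            assert np.array_equal(pa, pb)

    def test_best_so_far_history_is_nondecreasing(self):
        X, y, split = _separable_dataset(seed=2)
        model = train_mlp(X, y, split, 50, RpropConfig(max_epochs=100), seed=0)
        assert all(b >= a for a, b in zip(model.score_history,
                                          model.score_history[1:]))

    def test_overlapping_split_rejected(self):
        X, y, _ = _separable_dataset()
        with pytest.raises(ValidationError):
            train_mlp(X, y, {"learn": [0, 1, 2], "val": [2, 3]}, 50)

    def test_outputs_within_unit_interval(self):
        X, y, split = _separable_dataset()
        model = train_mlp(X, y, split, 50, RpropConfig(max_epochs=30), seed=0)
        out = model.forward(X)
        assert out.min() > 0.0 and out.max() < 1.0


class TestSweepTrain:
    def test_degenerate_sweep_equals_single_training(self):
        X, y, split = _separable_dataset()
        cfg = RpropConfig(max_epochs=40)
        best, report = sweep_train(X, y, split, hidden_sizes=[50],
                                   n_restarts=1, base_seed=5, config=cfg)
        single = train_mlp(X, y, split, 50, cfg, seed=5)
        assert np.array_equal(best.W1, single.W1)
        assert np.array_equal(best.W2, single.W2)
        assert len(report) == 1

    def test_report_shape_and_best_consistency(self):
        X, y, split = _separable_dataset(seed=4)
        cfg = RpropConfig(max_epochs=25)
        best, report = sweep_train(X, y, split, hidden_sizes=[50, 100],
                                   n_restarts=2, base_seed=0, config=cfg)
        assert len(report) == 4
        assert best.validation_score == report["val_score"].max()

    def test_tie_breaks_toward_fewer_hidden_units(self):
        # force a universal tie by training zero epochs on balanced data
        X, y, split = _separable_dataset()
        cfg = RpropConfig(max_epochs=0)
        best, report = sweep_train(X, y, split, hidden_sizes=[50, 100, 150],
                                   n_restarts=2, base_seed=0, config=cfg)
        top = report["val_score"].max()
        first = report[report["val_score"] == top].iloc[0]
        assert best.n_hidden <= int(first["n_hidden"])


class TestClassifyImage:
    def test_suppressed_model_gives_all_false_map(self, experiment):
        from mcica.io_calibration import ODImage
        basis = experiment.basis
        model = experiment.model
        muted = MLPModel(W1=model.W1, b1=model.b1, W2=model.W2,
                         b2=model.b2 - 20.0)  # outputs pinned near zero
        img = ODImage(pixels=np.full((40, 40), 1.5))
        det = classify_image(muted, basis, img, ANALYZER_PRESETS["wta1"])
        assert det.mask.shape == (40, 40)
        assert not det.mask.any()

    def test_map_shape_and_margin(self, experiment):
        det = classify_image(experiment.model, experiment.basis,
                             experiment.test_images[0],
                             ANALYZER_PRESETS["wta1"])
        m = det.margin_px
        assert det.mask.shape == experiment.test_images[0].pixels.shape
        assert m == experiment.basis.window_px // 2
        assert not det.mask[:m].any() and not det.mask[-m:].any()
        assert not det.mask[:, :m].any() and not det.mask[:, -m:].any()

    def test_detections_enriched_on_true_objects(self, experiment):
        from mcica.phantom import PhantomSpec, generate_phantom
        od, truth = generate_phantom(PhantomSpec(seed=321))
        det = classify_image(experiment.model, experiment.basis, od,
                             ANALYZER_PRESETS["wta1"])
        on_mc = np.isin(truth.label_mask, (LABEL_CLUSTERED, LABEL_ISOLATED))
        rate_mc = det.mask[on_mc].mean()
        rate_bg = det.mask[truth.label_mask == LABEL_BACKGROUND].mean()
        assert rate_mc > 10 * max(rate_bg, 1e-6)

    def test_dimension_mismatch_rejected(self, experiment):
        from mcica.errors import ConfigError as CE
        from mcica.io_calibration import ODImage
        model = experiment.model
        bad = MLPModel(W1=np.zeros((model.n_in + 1, 4)), b1=np.zeros(4),
                       W2=np.zeros((4, 3)), b2=np.zeros(3))
        with pytest.raises(CE):
            classify_image(bad, experiment.basis,
                           ODImage(pixels=np.zeros((32, 32))),
                           ANALYZER_PRESETS["wta1"])
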