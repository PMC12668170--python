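"""U-Net architecture contracts, loss formulas, training loop, post-processing."""

import numpy as np
import pytest

import ventseg.unet as unet_mod
from ventseg.core import ConfigurationError, LeakageError, OnsetAnnotation, make_windows
from ventseg.nn.tensor import Tensor
from ventseg.simulate import SimConfig, synth_record
from ventseg.unet import (
    LossConfig,
    ModelConfig,
    TrainConfig,
    UNetSegmenter,
    build_model,
    dice_loss,
    focal_loss,
    load_model,
    postprocess_events,
    predict_record,
    save_model,
    total_loss,
    train,
)

from conftest import NOISEFREE

TINY = ModelConfig(depth=2, base_filters=4, convs_per_block=1, kernel_size=5,
                   bottleneck_dilations=(1, 2), input_len=64, output_len=32)


class TestArchitecture:
    def test_output_shapes_and_sigmoid_range(self, rng):
        model = build_model(ModelConfig(depth=4, base_filters=4, convs_per_block=1), seed=0)
        x = rng.normal(size=(3, 352, 2)).astype(np.float32)
        p_insp, p_exp = model.forward(x)
        assert p_insp.shape == (3, 176, 1) and p_exp.shape == (3, 176, 1)
        for p in (p_insp, p_exp):
            assert np.all(p.data > 0) and np.all(p.data < 1)

    def test_depth_divisibility_enforced(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            ModelConfig(depth=5, input_len=176, output_len=176)

    def test_pooling_arithmetic_deepest_length(self, rng):
        """Four stride-2 pools shrink 352 to 22 at the bottleneck."""
        model = build_model(ModelConfig(depth=4, base_filters=2, convs_per_block=1), seed=0)
        x = Tensor(rng.normal(size=(1, 352, 2)).astype(np.float32))
        h = x
        for block in model.enc_blocks:
            for conv in block:
                h = conv(h).leaky_relu(0.01)
            from ventseg.nn.tensor import maxpool1d
            h = maxpool1d(h, 2)
        assert h.shape[1] == 22

    def test_forward_is_deterministic_in_eval_mode(self, rng):
        model = build_model(TINY, seed=3)
        x = rng.normal(size=(2, 64, 2)).astype(np.float32)
        a, _ = model.forward(x)
        b, _ = model.forward(x)
        np.testing.assert_array_equal(a.data, b.data)


class TestLosses:
    def test_focal_reduces_to_bce_at_gamma_zero(self, rng):
        p = rng.uniform(0.05, 0.95, size=(4, 16))
        g = (rng.random((4, 16)) < 0.3).astype(float)
        bce = -np.mean(g * np.log(p) + (1 - g) * np.log(1 - p))
        assert focal_loss(p, g, alpha=1.0, gamma=0.0) == pytest.approx(bce, rel=1e-6)

    def test_focal_single_element_hand_value(self):
        # g=1, p=0.5, alpha=1, gamma=2: 0.25 * log 2
        assert focal_loss(np.array([0.5]), np.array([1.0]), 1.0, 2.0) == pytest.approx(
            0.25 * np.log(2.0), rel=1e-9
        )

    def test_focal_vanishes_for_perfect_prediction(self):
        g = np.array([0.0, 1.0, 1.0, 0.0])
        assert focal_loss(g.copy(), g) < 1e-5

    def test_dice_perfect_and_degenerate(self):
        g = np.zeros(176)
        g[13] = 1.0
        assert dice_loss(g.copy(), g) == pytest.approx(0.0, abs=1e-12)
        z = np.zeros(64)
        assert dice_loss(z, z) == pytest.approx(0.0, abs=1e-12)  # eps/eps

    def test_dice_total_disagreement_near_one(self):
        g = np.zeros(176)
        g[0] = 1.0
        p = 1.0 - g
        eps = 1e-6
        assert dice_loss(p, g, eps) == pytest.approx(1.0 - eps / (175 + 1 + eps), rel=1e-9)

    def test_dice_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros(4), np.zeros(5))

    def test_total_loss_sigma_one_is_plain_average(self):
        assert total_loss(0.8, 0.4) == pytest.approx(0.6)

    def test_total_loss_log_terms(self):
        cfg = LossConfig(sigma1=np.e, sigma2=np.e)
        assert total_loss(0.0, 0.0, cfg) == pytest.approx(2.0)

    def test_total_loss_monotone_in_components(self):
        assert total_loss(1.0, 1.0) < total_loss(1.5, 1.0) < total_loss(1.5, 1.5)

    def test_sigma_gradient_descent_converges_to_sigma_sq_equals_loss(self):
        """Stationary point of L/(2 s^2) + log s is s^2 = L."""
        for fixed in (1.0, 0.5, 2.0):
            s = [Tensor(np.zeros(()), requires_grad=True) for _ in range(2)]
            lf = Tensor(np.asarray(fixed))
            ld = Tensor(np.asarray(fixed))
            for _ in range(3000):
                loss = unet_mod._total_loss_graph(lf, ld, s[0], s[1])
                for t in s:
                    t.zero_grad()
                loss.backward()
                for t in s:
                    t.data = t.data - 0.01 * t.grad
            sigma_sq = np.exp(float(s[0].data))
            assert sigma_sq == pytest.approx(fixed, rel=1e-3)


def _tiny_cohort():
    cfg = SimConfig(n_patients=3, breaths_per_patient=8, seed=42, **NOISEFREE)
    return synth_record(cfg)


def _tiny_batches():
    records = _tiny_cohort()
    mk = lambda recs: unet_mod.WindowBatch.concatenate(
        [make_windows(r, 64, 32, 32) for r in recs]
    )
    return mk(records[:2]), mk(records[2:])


class TestTraining:
    def test_early_stopping_contract(self, monkeypatch):
        """Flat validation loss with patience 1 stops after epoch 2, keeping
        the epoch-1 weights."""
        losses = iter([1.0, 1.0, 1.0, 1.0])
        monkeypatch.setattr(unet_mod, "_evaluate_loss", lambda *a, **k: next(losses))
        train_b, val_b = _tiny_batches()
        _, history = train(
            train_b, val_b, TINY, None,
            TrainConfig(max_epochs=10, patience=1, seed=0),
        )
        assert history["n_epochs"] == 2
        assert history["best_epoch"] == 0

    def test_training_is_deterministic_given_seed(self):
        train_b, val_b = _tiny_batches()
        cfg = TrainConfig(max_epochs=2, patience=2, seed=5)
        _, h1 = train(train_b, val_b, TINY, None, cfg)
        _, h2 = train(train_b, val_b, TINY, None, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_overlapping_provenance_raises_leakage_error(self):
        train_b, _ = _tiny_batches()
        with pytest.raises(LeakageError):
            train(train_b, train_b, TINY, None, TrainConfig(max_epochs=1))

    def test_loss_decreases_on_tiny_problem(self):
        train_b, val_b = _tiny_batches()
        _, history = train(train_b, val_b, TINY, None, TrainConfig(max_epochs=6, seed=1))
        assert history["val_loss"][-1] < history["val_loss"][0]

    def test_per_head_sigma_variant_trains(self):
        train_b, val_b = _tiny_batches()
        _, history = train(
            train_b, val_b, TINY, LossConfig(per_head_sigma=True),
            TrainConfig(max_epochs=2, seed=1),
        )
        assert len(history["val_loss"]) == 2


class TestInference:
    def test_probability_traces_cover_record(self):
        record = _tiny_cohort()[0]
        model = build_model(TINY, seed=0)
        pred = predict_record(model, record)
        assert len(pred.p_insp) == len(record) and len(pred.p_exp) == len(record)

    def test_zeroed_model_gives_half_probability_and_no_events(self):
        record = _tiny_cohort()[0]
        model = build_model(TINY, seed=0)
        model.load_state_dict({str(i): np.zeros_like(p.data) for i, p in enumerate(model.parameters())})
        pred = predict_record(model, record)
        np.testing.assert_allclose(pred.p_insp, 0.5, atol=1e-7)
        assert pred.events.insp_onsets.size == 0  # threshold is a strict >

    def test_save_load_roundtrip(self, tmp_path):
        model = build_model(TINY, seed=4)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        x = np.random.default_rng(0).normal(size=(1, 64, 2)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x)[0].data, back.forward(x)[0].data)


class TestPostprocess:
    def test_max_probability_exp_per_interval(self):
        p_insp = np.zeros(200)
        p_insp[[20, 120]] = 0.9
        p_exp = np.zeros(200)
        p_exp[60], p_exp[90] = 0.8, 0.6
        ann = postprocess_events(p_insp, p_exp)
        np.testing.assert_array_equal(ann.insp_onsets, [20, 120])
        np.testing.assert_array_equal(ann.exp_onsets, [60])

    def test_debounce_keeps_highest(self):
        p_insp = np.zeros(200)
        p_insp[100], p_insp[102] = 0.9, 0.7
        ann = postprocess_events(p_insp, np.zeros(200), debounce=5)
        np.testing.assert_array_equal(ann.insp_onsets, [100])

    def test_flat_subthreshold_traces_give_no_events(self):
        ann = postprocess_events(np.full(100, 0.4), np.full(100, 0.4))
        assert ann.insp_onsets.size == 0 and ann.exp_onsets.size == 0

    def test_open_segment_exp_kept_only_if_unique(self):
        p_insp = np.zeros(300)
        p_insp[150] = 0.9
        p_exp = np.zeros(300)
        p_exp[[30, 80]] = 0.8  # two candidates before the first insp: dropped
        p_exp[200] = 0.7  # single candidate after the last insp: kept
        ann = postprocess_events(p_insp, p_exp)
        np.testing.assert_array_equal(ann.exp_onsets, [200])

    def test_output_always_satisfies_annotation_invariants(self, rng):
        for _ in range(20):
            p_insp = rng.random(400) * rng.random()
            p_exp = rng.random(400) * rng.random()
            ann = postprocess_events(p_insp, p_exp)
            ann.validate(400)  # pairing constraints must hold for any input


class TestEstimator:
    def test_get_set_params_roundtrip(self):
        seg = UNetSegmenter(base_filters=4)
        params = seg.get_params()
        assert params["base_filters"] == 4
        seg.set_params(max_epochs=7)
        assert seg.max_epochs == 7

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            UNetSegmenter().predict_proba(_tiny_cohort()[0])

    def test_fit_with_internal_patient_split(self):
        records = _tiny_cohort()
        seg = UNetSegmenter(
            depth=2, base_filters=2, convs_per_block=1, kernel_size=5,
            bottleneck_dilations=(1, 2), input_len=64, output_len=32,
            max_epochs=2, seed=0,
        )
        seg.fit(records)
        assert seg.n_epochs_ == 2
        ann = seg.predict(records[0])
        assert isinstance(ann, OnsetAnnotation)
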