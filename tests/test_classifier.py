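"""Classifier: loss oracles, receptive field, staged training contracts."""

import dataclasses

import numpy as np
import pytest

from advcad import autodiff as ad
from advcad import classifier as cl
from advcad import nn
from advcad.autodiff import Tensor
from .conftest import tiny_config
from advcad import phantom as ph


class LinearScore:
    """Stub model whose per-sample score is w . x (flattened)."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def __call__(self, x):
        b = x.shape[0]
        flat = ad.reshape(x, (b, -1))
        return ad.reshape(flat @ Tensor(self.w.reshape(-1, 1)), (b,))


class TestFocalLoss:
    def test_perfect_probabilities_give_zero(self):
        assert cl.focal_loss([1.0, 1.0, 1.0], gamma=2).item() == 0.0

    def test_gamma_zero_reduces_to_mean_nll(self, rng):
        p = rng.uniform(0.1, 0.9, size=6)
        assert np.isclose(cl.focal_loss(p, gamma=0).item(), -np.log(p).mean())

    def test_single_probability_closed_form(self):
        # p = 0.5, gamma = 2: (1-p)^2 * (-ln p) = 0.25 * ln 2
        assert np.isclose(cl.focal_loss([0.5], gamma=2).item(), 0.25 * np.log(2))

    def test_elementwise_hand_evaluation(self, rng):
        p = rng.uniform(0.05, 0.99, size=8)
        expected = np.mean((1 - p) ** 2 * (-np.log(p)))
        assert np.isclose(cl.focal_loss(p, gamma=2).item(), expected)

    def test_probability_zero_is_clamped_and_logged(self, caplog):
        with caplog.at_level("WARNING"):
            val = cl.focal_loss([0.0], gamma=2).item()
        assert np.isfinite(val)
        assert "clamped" in caplog.text

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            cl.focal_loss([1.2])


class TestGradientPenalty:
    def test_constant_model_gives_zero(self, rng):
        const = lambda x: Tensor(np.zeros(x.shape[0]))
        xa, xb = rng.normal(size=(3, 1, 4, 4)), rng.normal(size=(3, 1, 4, 4))
        assert cl.input_gradient_penalty(const, xa, xb).item() == 0.0

    def test_linear_model_closed_form(self, rng):
        w = rng.normal(size=(2, 4, 4))
        model = LinearScore(w)
        xa, xb = rng.normal(size=(3, 2, 4, 4)), rng.normal(size=(3, 2, 4, 4))
        # every per-sample gradient is w, so GP = k * ||w||^o
        got = cl.input_gradient_penalty(model, xa, xb, k=10, o=4).item()
        assert np.isclose(got, 10 * np.linalg.norm(w) ** 4, rtol=1e-9)

    def test_matches_finite_difference_norms_on_conv_model(self, rng):
        torch_free = nn.Sequential(
            nn.Conv2d(1, 2, 3, padding=1, rng=rng), nn.LeakyReLU(0.2))
        lin = nn.Linear(2, 1, rng=rng)

        def score(x):
            feats = ad.global_max_pool(torch_free(x))
            return ad.reshape(lin(feats), (x.shape[0],))

        batch = rng.normal(size=(2, 1, 5, 5))
        k, o = 10.0, 4.0
        got = cl.input_gradient_penalty(score, batch, batch, k=k, o=o).item()

        # independent oracle: central differences for each per-sample gradient
        eps = 1e-5
        total = 0.0
        for j in range(batch.shape[0]):
            g = np.zeros_like(batch[j])
            it = np.nditer(batch[j], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                bp, bm = batch.copy(), batch.copy()
                bp[(j,) + idx] += eps
                bm[(j,) + idx] -= eps
                g[idx] = (score(Tensor(bp)).data[j] - score(Tensor(bm)).data[j]) / (2 * eps)
            total += 2 * np.linalg.norm(g) ** o   # both batches identical
        expected = k / (2 * batch.shape[0]) * total
        assert abs(got - expected) / expected < 1e-3

    def test_unequal_batches_raise(self, rng):
        model = LinearScore(rng.normal(size=(1, 2, 2)))
        with pytest.raises(ValueError):
            cl.input_gradient_penalty(model, rng.normal(size=(2, 1, 2, 2)),
                                      rng.normal(size=(3, 1, 2, 2)))


@pytest.fixture(scope="module")
def model():
    return cl.CadClassifier(seed=0).eval()


@pytest.fixture(scope="module")
def batches():
    r = np.random.default_rng(4)
    return (r.normal(size=(2, 3, 16, 16)), r.normal(size=(2, 3, 16, 16)))


class TestClassifierLoss:

    def test_additivity_against_components(self, model, batches):
        bp, bn = batches
        params = cl.ClassifierLossParams(n_per_class=2)
        loss, parts = cl.classifier_loss(model, bp, bn, params)
        prob_p = model(Tensor(bp)).data[:, 1]
        prob_n = model(Tensor(bn)).data[:, 0]
        fl_p = cl.focal_loss(prob_p, params.gamma).item()
        fl_n = cl.focal_loss(prob_n, params.gamma).item()
        gp = cl.input_gradient_penalty(model.score_positive, bp, bn,
                                       k=params.k, o=params.o).item()
        assert np.isclose(loss.item(), fl_p + fl_n + gp, rtol=1e-9)
        assert np.isclose(parts["focal_pos"], fl_p)
        assert np.isclose(parts["gradient_penalty"], gp, rtol=1e-9)

    def test_finite_and_positive_at_initialization(self, model, batches):
        loss, _ = cl.classifier_loss(model, *batches,
                                     cl.ClassifierLossParams(n_per_class=2))
        assert np.isfinite(loss.item()) and loss.item() > 0

    def test_focal_term_decreases_when_a_probability_increases(self):
        base = np.array([0.4, 0.6, 0.7, 0.5])
        bumped = base.copy()
        bumped[0] += 0.1
        assert cl.focal_loss(bumped, 2).item() < cl.focal_loss(base, 2).item()


class TestReceptiveField:
    def test_single_conv(self):
        assert cl.receptive_field([("conv", 3, 1, 1)]) == 3

    def test_two_stacked_convs(self):
        assert cl.receptive_field([("conv", 3, 1, 1), ("conv", 3, 1, 1)]) == 5

    def test_full_vgg11_stack_reaches_406(self):
        assert cl.receptive_field(cl.full_backbone().layers) == 406

    def test_desk_stack_covers_lesion_extent(self):
        spec = cl.desk_backbone()
        rf = cl.receptive_field(spec.layers)
        assert rf == spec.target_receptive_field
        lesion = ph.PhantomConfig().lesion
        max_extent = 2 * (lesion.radius_range[1] + lesion.spicule_length_range[1])
        assert rf >= max_extent

    def test_unknown_layer_kind_raises(self):
        with pytest.raises(ValueError):
            cl.receptive_field([("attention", 3, 1, 1)])

    def test_mismatched_target_rejected(self):
        with pytest.raises(ValueError):
            cl.BackboneSpec(mode="desk", layers=[("conv", 3, 1, 1)],
                            target_receptive_field=5).validate()


class TestPrediction:
    def test_softmax_outputs_sum_to_one(self, rng):
        model = cl.CadClassifier(seed=1).eval()
        probs = model(Tensor(rng.normal(size=(4, 3, 16, 16)))).data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_inference_is_deterministic(self, tiny_cohort):
        model = cl.CadClassifier(seed=1)
        img = tiny_cohort.test[0]
        assert cl.predict_prob(model, img) == cl.predict_prob(model, img)

    def test_zeroed_final_layer_gives_half(self, tiny_cohort):
        model = cl.CadClassifier(seed=1)
        final = model.fnet_fc.layers[-1]
        final.weight.data[:] = 0.0
        final.bias.data[:] = 0.0
        assert cl.predict_prob(model, tiny_cohort.test[0]) == 0.5


class TestTraining:
    def test_single_class_training_data_raises(self, tiny_cohort):
        negatives_only = dataclasses.replace(
            tiny_cohort,
            train=[im for im in tiny_cohort.train if im.label == "negative"])
        with pytest.raises(ValueError):
            cl.train_classifier(negatives_only)

    def test_stage1_freezes_backbone_and_stage2_unfreezes(self, tiny_cohort):
        opt = cl.OptimizerSpec(head_only_epochs=2, total_epochs=3,
                               lr_head=1e-3, lr_backbone=1e-3)
        # run stage-1-only training first and compare against fresh init
        opt1 = dataclasses.replace(opt, total_epochs=2)
        t1 = cl.train_classifier(tiny_cohort, opt=opt1, seed=9, select="last")
        with ad.default_dtype(np.float32):
            fresh_state = cl.CadClassifier(cl.desk_backbone(), seed=9).state_dict()
        trained_state = t1.model.state_dict()
        for k in trained_state:
            if k.startswith("vnet."):
                assert np.array_equal(trained_state[k], fresh_state[k]), k
        # head must have moved
        assert any(not np.array_equal(trained_state[k], fresh_state[k])
                   for k in trained_state if k.startswith("fnet"))
        # after stage 2 the backbone moves too
        t2 = cl.train_classifier(tiny_cohort, opt=opt, seed=9, select="last")
        s2 = t2.model.state_dict()
        assert any(not np.array_equal(s2[k], fresh_state[k])
                   for k in s2 if k.startswith("vnet."))
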