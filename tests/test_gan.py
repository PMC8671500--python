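"""GAN losses (closed forms), pseudo-color, training-phase contracts."""

import dataclasses

import numpy as np
import pytest

from advcad import autodiff as ad
from advcad import classifier as cl
from advcad import gan
from advcad import nn
from advcad import phantom as ph
from advcad.autodiff import Tensor
from .conftest import tiny_config


@pytest.fixture(scope="module")
def discriminator():
    return gan.make_discriminator(cl.CadClassifier(seed=2), seed=2).eval()


@pytest.fixture(scope="module")
def constant_discriminator():
    """All final-layer weights zero: raw score 0 for any input, zero input
    gradient."""
    dis = gan.make_discriminator(cl.CadClassifier(seed=2), seed=2).eval()
    final = dis.fnet_fc.layers[-1]
    final.weight.data[:] = 0.0
    final.bias.data[:] = 0.0
    return dis


class LinearRaw:
    """Stub discriminator: raw score w . x."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def logits(self, x):
        return ad.reshape(x, (x.shape[0], -1)) @ Tensor(self.w.reshape(-1, 1))


class TestDisScore:
    def test_raw_zero_scores_minus_ln2(self, constant_discriminator, rng):
        x = Tensor(rng.normal(size=(2, 3, 16, 16)))
        scores = gan.dis_score(constant_discriminator, x)
        assert np.allclose(scores.data, -np.log(2))

    def test_score_is_log_sigmoid_of_raw_and_nonpositive(self, discriminator, rng):
        x = Tensor(rng.normal(size=(3, 3, 16, 16)))
        raw = gan.dis_raw(discriminator, x).data
        score = gan.dis_score(discriminator, x).data
        assert np.allclose(score, -np.log1p(np.exp(-raw)))
        assert (score <= 0).all()

    def test_monotone_in_raw_score(self, constant_discriminator, rng):
        dis = constant_discriminator
        x = Tensor(rng.normal(size=(1, 3, 16, 16)))
        final = dis.fnet_fc.layers[-1]
        scores = []
        for bias in (-1.0, 0.0, 2.0):
            final.bias.data[:] = bias
            scores.append(float(gan.dis_score(dis, x).data[0]))
        final.bias.data[:] = 0.0
        assert scores[0] < scores[1] < scores[2]


class TestLossDis:
    def test_reduces_to_abs_d_minus_one_for_constant_discriminator(
            self, constant_discriminator, rng):
        # Dis(x) = Dis(y_fn) = -ln 2 and GP = 0, so the loss is |d - 1|
        x = rng.normal(size=(2, 3, 16, 16))
        yfn = rng.normal(size=(2, 3, 16, 16))
        loss, parts = gan.loss_dis(constant_discriminator, x, yfn)
        d = -np.log(2)
        assert np.isclose(loss.item(), abs(d - 1), rtol=1e-6)
        assert np.isclose(parts["gp"], 0.0, atol=1e-12)

    def test_additivity_of_gp_term(self, discriminator, rng):
        x = rng.normal(size=(2, 3, 16, 16))
        yfn = rng.normal(size=(2, 3, 16, 16))
        loss, parts = gan.loss_dis(discriminator, x, yfn)
        gp = gan.gp_dis(discriminator, x).item()
        assert np.isclose(parts["gp"], gp, rtol=1e-6)
        reconstructed = (-parts["dis_x"] + parts["dis_yfn"]
                         + parts["stabilizer"] + gp)
        assert np.isclose(loss.item(), reconstructed, rtol=1e-6)

    def test_mismatched_batches_raise(self, discriminator, rng):
        with pytest.raises(ValueError):
            gan.loss_dis(discriminator, rng.normal(size=(2, 3, 16, 16)),
                         rng.normal(size=(3, 3, 16, 16)))


class TestGpDis:
    def test_constant_discriminator_gives_zero(self, constant_discriminator, rng):
        x = rng.normal(size=(2, 3, 16, 16))
        assert np.isclose(gan.gp_dis(constant_discriminator, x).item(), 0.0,
                          atol=1e-12)

    def test_linear_raw_score_closed_form(self, rng):
        w = rng.normal(size=(3, 8, 8))
        x = rng.normal(size=(4, 3, 8, 8))
        got = gan.gp_dis(LinearRaw(w), x, gan.GanLossParams(k=10, o=4)).item()
        assert np.isclose(got, 5 * np.linalg.norm(w) ** 4, rtol=1e-9)

    def test_matches_finite_differences_on_toy_model(self, rng):
        conv = nn.Conv2d(1, 2, 3, padding=1, rng=rng)
        lin = nn.Linear(2, 1, rng=rng)

        class Toy:
            def logits(self, x):
                return lin(ad.global_max_pool(ad.leaky_relu(conv(x), 0.2)))

        toy = Toy()
        x = rng.normal(size=(2, 1, 5, 5))
        got = gan.gp_dis(toy, x).item()
        eps = 1e-5
        norms = []
        for j in range(2):
            g = np.zeros_like(x[j])
            it = np.nditer(x[j], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                xp, xm = x.copy(), x.copy()
                xp[(j,) + idx] += eps
                xm[(j,) + idx] -= eps
                fj = lambda v: float(toy.logits(Tensor(v)).data[j, 0])
                g[idx] = (fj(xp) - fj(xm)) / (2 * eps)
            norms.append(np.linalg.norm(g))
        expected = 10 / 2 * np.mean([n ** 4 for n in norms])
        assert abs(got - expected) / expected < 1e-3


class TestLossGen:
    def test_perfect_reconstruction_is_zero(self, rng):
        y = rng.normal(size=(3, 8, 8))
        assert gan.loss_gen1(Tensor(y.copy()), Tensor(y)).item() == 0.0

    def test_zero_output_gives_one(self, rng):
        y = rng.normal(size=(3, 8, 8))
        assert np.isclose(gan.loss_gen1(Tensor(np.zeros_like(y)), Tensor(y)).item(), 1.0)

    def test_doubled_output_gives_one(self, rng):
        y = rng.normal(size=(3, 8, 8))
        assert np.isclose(gan.loss_gen1(Tensor(2 * y), Tensor(y)).item(), 1.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            gan.loss_gen1(Tensor(np.ones((2, 2))), Tensor(np.zeros((2, 2))))

    def test_loss_gen2_additivity(self, discriminator, rng):
        yfn = rng.normal(size=(2, 3, 16, 16))
        y = rng.normal(size=(2, 3, 16, 16))
        total = gan.loss_gen2(discriminator, Tensor(yfn), Tensor(y)).item()
        parts = (-gan.dis_score(discriminator, Tensor(yfn)).data.mean()
                 + gan.loss_gen1(Tensor(yfn), Tensor(y)).item())
        assert np.isclose(total, parts, rtol=1e-6)


class TestPseudoColor:
    def test_channels_are_affine_images_of_the_plane(self, rng):
        plane = rng.random((2, 1, 8, 8))
        out = gan.pseudo_color(Tensor(plane)).data
        for c in range(3):
            assert np.allclose(out[:, c],
                               (plane[:, 0] - ph.VGG_MEAN[c]) / ph.VGG_SD[c])

    def test_inverse_standardization_recovers_plane(self, rng):
        plane = rng.random((1, 1, 6, 6))
        out = gan.pseudo_color(Tensor(plane)).data
        back = np.stack([out[:, c] * ph.VGG_SD[c] + ph.VGG_MEAN[c]
                         for c in range(3)]).mean(axis=0)
        assert np.allclose(back, plane[:, 0], atol=1e-6)

    def test_constant_input_gives_constant_channels(self):
        out = gan.pseudo_color(Tensor(np.full((1, 1, 4, 4), 0.5))).data
        for c in range(3):
            assert np.allclose(out[0, c], out[0, c].flat[0])

    def test_out_of_range_input_raises(self):
        with pytest.raises(ValueError):
            gan.pseudo_color(Tensor(np.full((1, 1, 2, 2), 1.5)))

    def test_differentiable_pass_through(self, rng):
        plane = Tensor(rng.random((1, 1, 4, 4)))
        g = ad.grad((gan.pseudo_color(plane) ** 2).sum(), plane)
        assert g.data.shape == plane.shape and np.abs(g.data).max() > 0


@pytest.fixture(scope="module")
def tiny_gan_run(gan_cohort):
    """One short two-direction-capable run used by several contract tests."""
    opt = cl.OptimizerSpec(head_only_epochs=1, total_epochs=3,
                           lr_head=3e-4, lr_backbone=3e-4)
    trained = cl.train_classifier(gan_cohort, opt=opt, seed=6)
    sched = gan.GanSchedule(
        phase_a=gan.PhaseSpec(3e-4, 0.002, 2),
        phase_b=gan.PhaseSpec(3e-4, 0.2, 2),
        phase_c_epoch_cap=4, lr_gen_c=1e-4,
        lr_dis_head=3e-4, lr_dis_backbone=1e-4,
        phase_c_margin_stop=1e-9)  # effectively run all phase-C epochs
    g = gan.train_gan("remove_lesion", gan_cohort, trained,
                      schedule=sched, seed=6)
    return trained, g


class TestTrainingContracts:
    def test_phase_b_freezes_everything_but_final_layer(self, tiny_gan_run):
        _, g = tiny_gan_run
        assert g.phase_b_frozen_delta == 0.0

    def test_phase_c_updates_generator_once_per_five_batches(self, tiny_gan_run):
        _, g = tiny_gan_run
        seq = g.update_log
        assert seq.count("gen") == seq.count("dis") // 5 > 0
        dis_since_gen = 0
        for ev in seq:
            if ev == "dis":
                dis_since_gen += 1
            else:
                assert dis_since_gen == 5
                dis_since_gen = 0

    def test_phase_log_records_margins_and_losses(self, tiny_gan_run):
        _, g = tiny_gan_run
        phases = g.log["phase"].tolist()
        assert phases == sorted(phases)  # A then B then C
        a_rows = g.log[g.log.phase == "A"]
        assert a_rows["loss_gen1"].notna().all()
        assert g.log[g.log.phase != "A"]["margin"].notna().all()

    def test_direction_mismatch_raises(self, tiny_gan_run, tiny_cohort):
        _, g = tiny_gan_run
        neg = next(i for i in tiny_cohort.test if i.label == "negative")
        with pytest.raises(ValueError):
            gan.generate_adversarial(g, neg)

    def test_generated_fake_contract(self, tiny_gan_run, tiny_cohort):
        _, g = tiny_gan_run
        pos = next(i for i in tiny_cohort.train if i.label == "positive")
        pair = gan.generate_adversarial(g, pos)
        assert pair.fake.label == "negative"
        assert pair.fake.realness == "fake"
        assert pair.fake.pixels.shape == pos.pixels.shape
        assert pair.fake.pixels.dtype == np.uint16
        again = gan.generate_adversarial(g, pos)
        assert np.array_equal(pair.fake.pixels, again.fake.pixels)

    def test_invalid_direction_rejected(self, tiny_gan_run, tiny_cohort):
        trained, _ = tiny_gan_run
        with pytest.raises(ValueError):
            gan.train_gan("sideways", tiny_cohort, trained)

    def test_insert_direction_swaps_roles(self, tiny_gan_run, tiny_cohort):
        trained, _ = tiny_gan_run
        sched = gan.GanSchedule(
            phase_a=gan.PhaseSpec(3e-4, 0.002, 1),
            phase_b=gan.PhaseSpec(3e-4, 0.2, 1),
            phase_c_epoch_cap=1, lr_gen_c=1e-4,
            lr_dis_head=3e-4, lr_dis_backbone=1e-4)
        g = gan.train_gan("insert_lesion", tiny_cohort, trained,
                          schedule=sched, seed=6)
        neg = next(i for i in tiny_cohort.test if i.label == "negative")
        pair = gan.generate_adversarial(g, neg)
        assert pair.fake.label == "positive"


class TestDiscriminatorInit:
    def test_copies_classifier_weights_except_final_layer(self):
        clf = cl.CadClassifier(seed=7)
        dis = gan.make_discriminator(clf, seed=7)
        clf_state = clf.state_dict()
        dis_state = dis.state_dict()
        for key, val in dis_state.items():
            if key.startswith("fnet_fc.3."):
                assert val.shape[-1] == 1  # one output neuron
            else:
                assert np.array_equal(val, clf_state[key]), key
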