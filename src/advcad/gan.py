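"""Adversarial image generation: U-Net generator, discriminator, 3-phase GAN.

Two independent GANs produce the label-flipped counterfeits: one removes
lesion tissue from positives (negative-looking fakes), one inserts
lesion-like tissue into negatives (positive-looking fakes). The module is
written for the removal direction — ``x`` denotes real target-class images
(negatives), ``y`` the source-class images (positives), and ``y_fn`` the
3-channel pseudo-color fake generated from Gnet(y) — and the insertion
direction simply swaps which class plays x and which plays y.

Losses (batch means):

    Loss_dis  = -Dis(x) + Dis(y_fn) + |Dis(x) - 1|_1 + GP(x)
    Dis(g)    = -ln(1 + exp(-Dnet(Vnet(g))))            (log-sigmoid score)
    GP(x)     = k/2 * ||grad_x Dnet(Vnet(x))||_2^o       (k=10, o=4)
    Loss_gen1 = ||y_fn - y||_2^2 / ||y||_2^2             (identity loss)
    Loss_gen2 = -Dis(y_fn) + Loss_gen1                   (adversarial loss)

The |Dis(x)-1| stabilizer anchors the discriminator's real-image scores, and
the identity term keeps the generator faithful outside the (small) lesion.

Training is staged: (A) the generator alone learns the identity mapping
until the epoch-mean identity loss falls below a threshold (0.002) or an
epoch cap (11); (B) only the discriminator's final layer trains until the
real-minus-fake score margin exceeds 0.2 or 10 epochs; (C) generator and
discriminator alternate — one generator update per 5 discriminator batches —
until the margin closes below 0.01 or an epoch cap. Phase A/B thresholds are
epoch means; the phase-C margin is an epoch-length sliding mean checked at
every batch. The discriminator shares the classifier's architecture with a
single output neuron and is initialized from the trained classifier; its
scoring layer starts at the classifier's class-difference direction (see
:func:`make_discriminator`).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .classifier import BackboneSpec, CadClassifier, TrainedClassifier, desk_backbone
from .phantom import (
    VGG_MEAN,
    VGG_SD,
    DatasetSplit,
    PhantomImage,
    augment,
    normalize_for_model,
    unit_to_u16,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """U-Net topology: average-pool downsampling, bilinear x2 upsampling,
    sigmoid-normalized single-channel output."""
    channels: tuple[int, int, int] = (8, 16, 32)
    depth: int = 2  # number of pool/upsample levels


@dataclass
class GanLossParams:
    k: float = 10.0
    o: float = 4.0

    def validate(self):
        if self.k <= 0 or self.o < 1:
            raise ValueError("invalid gradient-penalty parameters")
        return self


@dataclass
class PhaseSpec:
    lr: float
    threshold: float
    epoch_cap: int


@dataclass
class GanSchedule:
    """Three-phase schedule; thresholds are epoch-mean statistics.

    Phase A: generator identity training, stop when Loss_gen1 < 0.002.
    Phase B: discriminator final layer only, stop when margin > 0.2.
    Phase C: alternating, generator once per 5 batches, stop when
    margin < 0.01. The margin is mean Dis(x) - mean Dis(y_fn); in phase C
    it is an epoch-length sliding mean over the training batches, checked
    every batch (see the trainer for why the stop must not lag the
    crossing).
    """
    phase_a: PhaseSpec = field(default_factory=lambda: PhaseSpec(1e-4, 0.002, 11))
    phase_b: PhaseSpec = field(default_factory=lambda: PhaseSpec(1e-4, 0.2, 10))
    phase_c_margin_stop: float = 0.01
    phase_c_epoch_cap: int = 200
    lr_gen_c: float = 1e-5
    lr_dis_head: float = 1e-4
    lr_dis_backbone: float = 1e-5
    gen_update_every: int = 5
    beta1: float = 0.5
    beta2: float = 0.9
    batch_size: int = 4

    def validate(self):
        if min(self.phase_a.threshold, self.phase_b.threshold,
               self.phase_c_margin_stop) <= 0:
            raise ValueError("phase thresholds must be positive")
        return self


def desk_gan_schedule() -> GanSchedule:
    """Schedule scaled for the desk networks (no pretrained backbone, few
    optimization steps per epoch): larger generator/discriminator head
    rates, a near-frozen discriminator backbone so the discriminator stays
    aligned with the classifier it was initialized from, and a short
    phase-C cap."""
    return GanSchedule(
        phase_a=PhaseSpec(3e-4, 0.002, 11),
        phase_b=PhaseSpec(1e-3, 0.2, 10),
        phase_c_epoch_cap=20,
        lr_gen_c=1e-3,
        lr_dis_head=3e-4,
        lr_dis_backbone=1e-5,
    )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class UNetGenerator(nn.Module):
    """Two-level U-Net with skip connections; sigmoid output in (0, 1).

    The pre-sigmoid output adds the logit of the input plane (a residual
    passthrough), so the untrained network is already close to the identity
    mapping and training concentrates on the modification the adversarial
    objective demands. The output is still sigmoid-normalized to [0, 1].
    """

    def __init__(self, spec: GeneratorSpec | None = None, seed: int = 0):
        super().__init__()
        self.spec = spec or GeneratorSpec()
        c1, c2, c3 = self.spec.channels
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E7]))
        self.enc1 = nn.Sequential(nn.Conv2d(1, c1, 3, padding=1, rng=rng),
                                  nn.LeakyReLU(0.2))
        self.enc2 = nn.Sequential(nn.Conv2d(c1, c2, 3, padding=1, rng=rng),
                                  nn.LeakyReLU(0.2))
        self.bottleneck = nn.Sequential(nn.Conv2d(c2, c3, 3, padding=1, rng=rng),
                                        nn.LeakyReLU(0.2))
        self.dec2 = nn.Sequential(nn.Conv2d(c3 + c2, c2, 3, padding=1, rng=rng),
                                  nn.LeakyReLU(0.2))
        self.dec1 = nn.Sequential(nn.Conv2d(c2 + c1, c1, 3, padding=1, rng=rng),
                                  nn.LeakyReLU(0.2))
        self.out_conv = nn.Conv2d(c1, 1, 3, padding=1, rng=rng)
        # small initial modification head: the fresh network stays close to
        # the identity provided by the logit passthrough
        self.out_conv.weight.data *= 0.1

    def forward(self, x: Tensor) -> Tensor:
        """(B, 1, H, W) normalized single channel -> (B, 1, H, W) in (0, 1)."""
        e1 = self.enc1(x)
        e2 = self.enc2(ad.avg_pool2d(e1, 2, 2))
        b = self.bottleneck(ad.avg_pool2d(e2, 2, 2))
        d2 = self.dec2(ad.concat([ad.upsample_bilinear_2x(b), e2], axis=1))
        d1 = self.dec1(ad.concat([ad.upsample_bilinear_2x(d2), e1], axis=1))
        # logit of the (clamped) input plane: the identity passthrough
        plane = x * float(VGG_SD[0]) + float(VGG_MEAN[0])
        clamped = np.clip(plane.data, 1e-4, 1.0 - 1e-4)
        gate = Tensor((plane.data > 1e-4) & (plane.data < 1.0 - 1e-4))
        p = plane * gate + Tensor(np.where(gate.data > 0, 0.0, clamped))
        skip = ad.log(p) - ad.log(Tensor(1.0) - p)
        return ad.sigmoid(self.out_conv(d1) + skip)


def make_discriminator(classifier: TrainedClassifier | CadClassifier,
                       seed: int = 0,
                       score_class: int | None = None) -> CadClassifier:
    """Classifier-shaped network with one output neuron, initialized from
    the trained classifier.

    With ``score_class=None`` the final layer starts random. With
    ``score_class`` 0 (negative) or 1 (positive), the scoring layer is
    initialized to the classifier's class-difference direction, so the raw
    score starts as the logit contrast "looks like class c minus looks like
    the other class". This keeps the discriminator's verdict commensurate
    with the classifier's decision function: a randomly initialized scoring
    layer separates real from fake only shallowly, and the generator can
    then win with perturbations far smaller than anything that would move
    the classifier.
    """
    src = classifier.model if isinstance(classifier, TrainedClassifier) else classifier
    dis = CadClassifier(src.spec, seed=seed, head_outputs=1)
    state = {k: v for k, v in src.state_dict().items()
             if not k.startswith("fnet_fc.3.")}
    own = dis.state_dict()
    own.update(state)
    dis.load_state_dict(own)
    if score_class is not None:
        w = src.fnet_fc.layers[-1].weight.data
        b = src.fnet_fc.layers[-1].bias.data
        other = 1 - score_class
        dis.fnet_fc.layers[-1].weight.data[:] = \
            (w[:, score_class] - w[:, other])[:, None]
        dis.fnet_fc.layers[-1].bias.data[:] = b[score_class] - b[other]
    return dis


def dis_raw(discriminator: CadClassifier, g: Tensor) -> Tensor:
    """Raw score Dnet(Vnet(g)) per sample, shape (B,)."""
    lg = discriminator.logits(g)
    return ad.reshape(lg, (lg.shape[0],))


def dis_score(discriminator: CadClassifier, g: Tensor) -> Tensor:
    """Dis(g) = -ln(1 + exp(-raw)): log-sigmoid of the raw score, <= 0."""
    return ad.log_sigmoid(dis_raw(discriminator, g))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _abs(t: Tensor) -> Tensor:
    return t * Tensor(np.sign(t.data) + (t.data == 0))


def gp_dis(discriminator: CadClassifier, x_batch,
           params: GanLossParams | None = None) -> Tensor:
    """GP(x) = k/2 * mean_j ||grad_{x_j} Dnet(Vnet(x_j))||_2^o."""
    params = (params or GanLossParams()).validate()
    x = Tensor(x_batch.data if isinstance(x_batch, Tensor)
               else np.asarray(x_batch, dtype=float))
    raw = dis_raw(discriminator, x)
    g = ad.grad(raw.sum(), x)
    sq = (g ** 2).sum(axis=tuple(range(1, g.ndim)))
    return (sq ** (params.o / 2.0)).mean() * (params.k / 2.0)


def loss_dis(discriminator: CadClassifier, x_batch, yfn_batch,
             params: GanLossParams | None = None) -> tuple[Tensor, dict]:
    """Discriminator loss, Eq above; returns (loss, detached components)."""
    params = (params or GanLossParams()).validate()
    x = x_batch if isinstance(x_batch, Tensor) else Tensor(np.asarray(x_batch, dtype=float))
    yfn = yfn_batch if isinstance(yfn_batch, Tensor) else Tensor(np.asarray(yfn_batch, dtype=float))
    if x.shape[0] != yfn.shape[0]:
        raise ValueError("real and fake batches must match in size")
    dis_x = dis_score(discriminator, x)
    dis_y = dis_score(discriminator, yfn)
    stabilizer = _abs(dis_x - Tensor(1.0)).mean()
    gp = gp_dis(discriminator, x, params)
    loss = -dis_x.mean() + dis_y.mean() + stabilizer + gp
    parts = {"dis_x": float(dis_x.data.mean()), "dis_yfn": float(dis_y.data.mean()),
             "stabilizer": stabilizer.item(), "gp": gp.item()}
    return loss, parts


def loss_gen1(y_fn: Tensor, y: Tensor) -> Tensor:
    """Relative squared reconstruction error ||y_fn - y||^2 / ||y||^2.

    For batched input the per-sample ratios are averaged.
    """
    y_fn = y_fn if isinstance(y_fn, Tensor) else Tensor(np.asarray(y_fn, dtype=float))
    y = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=float))
    if y_fn.shape != y.shape:
        raise ValueError("shapes must match")
    if y.ndim == 4:
        axes = (1, 2, 3)
        denom = (y ** 2).sum(axis=axes)
        if (denom.data == 0).any():
            raise ValueError("reference image(s) must not be all-zero")
        num = ((y_fn - y) ** 2).sum(axis=axes)
        return (num * denom ** -1.0).mean()
    denom = (y ** 2).sum()
    if denom.data == 0:
        raise ValueError("reference image must not be all-zero")
    return ((y_fn - y) ** 2).sum() * denom ** -1.0


def loss_gen2(discriminator: CadClassifier, y_fn: Tensor, y: Tensor) -> Tensor:
    """Adversarial + identity generator loss: -Dis(y_fn) + Loss_gen1."""
    y_fn = y_fn if isinstance(y_fn, Tensor) else Tensor(np.asarray(y_fn, dtype=float))
    return -dis_score(discriminator, y_fn).mean() + loss_gen1(y_fn, y)


def pseudo_color(gen_output: Tensor) -> Tensor:
    """Replicate a [0, 1] plane to 3 channels and standardize per channel.

    Differentiable pass-through used to feed generator output to the
    (3-channel) discriminator or classifier; inverse of the normalization
    recovers the input plane.
    """
    x = gen_output if isinstance(gen_output, Tensor) else Tensor(np.asarray(gen_output, dtype=float))
    if (x.data < 0).any() or (x.data > 1).any():
        raise ValueError("generator output must lie in [0, 1]")
    if x.ndim == 3:  # (B, H, W) -> (B, 1, H, W)
        x = ad.reshape(x, (x.shape[0], 1) + x.shape[1:])
    planes = [(x - float(VGG_MEAN[c])) * (1.0 / float(VGG_SD[c])) for c in range(3)]
    return ad.concat(planes, axis=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class AdversarialGenerator:
    model: UNetGenerator
    direction: str                   # "remove_lesion" | "insert_lesion"
    schedule: GanSchedule
    log: pd.DataFrame                # phase, epoch, loss_gen1, margin, ...
    update_log: list[str]            # per-batch "dis"/"gen" sequence (phase C)
    # max |delta| across phase B of parameters that must stay frozen there
    # (all generator params; all discriminator params except the final layer)
    phase_b_frozen_delta: float = float("nan")


@dataclass
class AdversarialPair:
    real: PhantomImage
    fake: PhantomImage
    direction: str

    def __post_init__(self):
        if self.real.label == self.fake.label:
            raise ValueError("fake must carry the flipped label")


def _gen_input(images: list[PhantomImage], rng=None) -> np.ndarray:
    """Augmented single-channel normalized batch for the generator."""
    arrs = []
    for img in images:
        px = img.pixels if rng is None else augment(img.pixels, rng)
        arrs.append(normalize_for_model(px, 1))
    return np.stack(arrs)


def _three_channel(images: list[PhantomImage] | None = None,
                   pixels_list: list[np.ndarray] | None = None) -> np.ndarray:
    if pixels_list is None:
        pixels_list = [img.pixels for img in images]
    return np.stack([normalize_for_model(px, 3) for px in pixels_list])


def train_gan(direction: str,
              split: DatasetSplit,
              classifier: TrainedClassifier,
              schedule: GanSchedule | None = None,
              loss_params: GanLossParams | None = None,
              gen_spec: GeneratorSpec | None = None,
              seed: int = 0,
              dtype: str = "float32",
              aligned_discriminator: bool = True) -> AdversarialGenerator:
    """Train one direction's generator with the three-phase schedule.

    ``direction="remove_lesion"``: y = positives, x = negatives (the fake
    should look negative). ``direction="insert_lesion"``: roles swapped.
    Sampling and augmentation mirror classifier training. By default the
    discriminator's scoring layer starts at the classifier's
    class-difference direction (see :func:`make_discriminator`).
    """
    if direction not in ("remove_lesion", "insert_lesion"):
        raise ValueError("direction must be remove_lesion or insert_lesion")
    schedule = (schedule or desk_gan_schedule()).validate()
    loss_params = (loss_params or GanLossParams()).validate()
    with ad.default_dtype(np.dtype(dtype)):
        return _train_gan_inner(direction, split, classifier, schedule,
                                loss_params, gen_spec, seed,
                                aligned_discriminator)


def _train_gan_inner(direction, split, classifier, schedule, loss_params,
                     gen_spec, seed, aligned_discriminator) -> AdversarialGenerator:
    pos = [im for im in split.train if im.label == "positive"]
    neg = [im for im in split.train if im.label == "negative"]
    if not pos or not neg:
        raise ValueError("training data must contain both classes")
    source, target = (pos, neg) if direction == "remove_lesion" else (neg, pos)

    gen = UNetGenerator(gen_spec, seed=seed)
    # the discriminator scores the target class as "real": negatives for the
    # removal direction, positives for insertion
    score_class = 0 if direction == "remove_lesion" else 1
    dis = make_discriminator(
        classifier, seed=seed,
        score_class=score_class if aligned_discriminator else None)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6A9]))
    n = schedule.batch_size
    records: list[dict] = []
    update_log: list[str] = []

    def batches(pool, steps):
        order = rng.permutation(len(pool))
        for s in range(steps):
            picked = [pool[i] for i in order[(s * n) % len(pool):][:n]]
            while len(picked) < n:
                picked.append(pool[rng.integers(len(pool))])
            yield picked

    steps_per_epoch = max(min(len(source), len(target)) // n, 1)
    # phase A touches only the source pool, so an identity epoch sweeps it all
    steps_phase_a = max(len(source) // n, 1)

    def epoch_margin() -> tuple[float, float]:
        """Mean Dis(x), Dis(y_fn) over a sweep of the training data (eval)."""
        gen.eval(), dis.eval()
        dx, dy = [], []
        for s in range(steps_per_epoch):
            src = [source[i] for i in rng.permutation(len(source))[:n]]
            tgt = [target[i] for i in rng.permutation(len(target))[:n]]
            yfn = pseudo_color(gen(Tensor(_gen_input(src))))
            dy.append(dis_score(dis, yfn).data.mean())
            dx.append(dis_score(dis, Tensor(_three_channel(tgt))).data.mean())
        gen.train(), dis.train()
        return float(np.mean(dx)), float(np.mean(dy))

    # ---- phase A: identity pretraining of the generator -------------------
    opt = nn.Adam([{"params": gen.parameters(), "lr": schedule.phase_a.lr}],
                  beta1=schedule.beta1, beta2=schedule.beta2)
    for epoch in range(schedule.phase_a.epoch_cap):
        losses = []
        for picked in batches(source, steps_phase_a):
            xin = _gen_input(picked, rng)
            # identity target: the [0, 1] plane the generator received,
            # replicated/standardized exactly like its output
            y3 = pseudo_color(Tensor(np.clip(
                xin[:, 0] * VGG_SD[0] + VGG_MEAN[0], 0.0, 1.0)))
            yfn = pseudo_color(gen(Tensor(xin)))
            l1 = loss_gen1(yfn, y3.detach())
            opt.step(nn.compute_grads(l1, gen.parameters()))
            losses.append(l1.item())
        mean_l1 = float(np.mean(losses))
        records.append({"phase": "A", "epoch": epoch, "loss_gen1": mean_l1,
                        "margin": np.nan})
        logger.info("GAN %s phase A epoch %d loss_gen1 %.5f",
                    direction, epoch, mean_l1)
        if mean_l1 < schedule.phase_a.threshold:
            break
    else:
        logger.warning("phase A hit its epoch cap before the %.3g threshold",
                       schedule.phase_a.threshold)

    # ---- phase B: discriminator final layer only ---------------------------
    final_layer = dis.fnet_fc.layers[-1].parameters()
    final_ids = {id(p) for p in final_layer}
    frozen_before = [(p, p.data.copy()) for p in gen.parameters() + dis.parameters()
                     if id(p) not in final_ids]
    opt = nn.Adam([{"params": final_layer, "lr": schedule.phase_b.lr}],
                  beta1=schedule.beta1, beta2=schedule.beta2)
    gen.eval()
    for epoch in range(schedule.phase_b.epoch_cap):
        for picked in batches(target, steps_per_epoch):
            src = [source[i] for i in rng.permutation(len(source))[:n]]
            with_no_gen_grad = pseudo_color(
                gen(Tensor(_gen_input(src, rng))).detach())
            x3 = Tensor(_three_channel_aug(picked, rng))
            ld, _ = loss_dis(dis, x3, with_no_gen_grad, loss_params)
            opt.step(nn.compute_grads(ld, final_layer))
        dx, dy = epoch_margin()
        margin = dx - dy
        records.append({"phase": "B", "epoch": epoch, "loss_gen1": np.nan,
                        "margin": margin})
        logger.info("GAN %s phase B epoch %d margin %.4f", direction, epoch, margin)
        if margin > schedule.phase_b.threshold:
            break
    else:
        logger.warning("phase B hit its epoch cap before margin > %.3g",
                       schedule.phase_b.threshold)
    phase_b_delta = max(
        (float(np.abs(p.data - before).max()) for p, before in frozen_before),
        default=0.0)
    gen.train()

    # ---- phase C: alternating adversarial training -------------------------
    opt_dis = nn.Adam([
        {"params": dis.fnet_conv.parameters() + dis.fnet_fc.parameters(),
         "lr": schedule.lr_dis_head},
        {"params": dis.vnet.parameters(), "lr": schedule.lr_dis_backbone},
    ], beta1=schedule.beta1, beta2=schedule.beta2)
    opt_gen = nn.Adam([{"params": gen.parameters(), "lr": schedule.lr_gen_c}],
                      beta1=schedule.beta1, beta2=schedule.beta2)
    batch_counter = 0
    # the stopping margin is an epoch-length sliding mean of the per-batch
    # training margins, checked at every batch: once the generator crosses,
    # its adversarial gradient saturates and the identity term starts to
    # undo the modification, so waiting until the end of an epoch to test
    # the margin would return a generator that has already retreated

    running = deque(maxlen=steps_per_epoch)
    for epoch in range(schedule.phase_c_epoch_cap):
        crossed = False
        for picked in batches(target, steps_per_epoch):
            src = [source[i] for i in rng.permutation(len(source))[:n]]
            xin = _gen_input(src, rng)
            x3 = Tensor(_three_channel_aug(picked, rng))
            yfn_detached = pseudo_color(gen(Tensor(xin)).detach())
            ld, parts = loss_dis(dis, x3, yfn_detached, loss_params)
            opt_dis.step(nn.compute_grads(
                ld, dis.parameters()))
            update_log.append("dis")
            running.append(parts["dis_x"] - parts["dis_yfn"])
            batch_counter += 1
            if batch_counter % schedule.gen_update_every == 0:
                yfn = pseudo_color(gen(Tensor(xin)))
                y3 = pseudo_color(Tensor(np.clip(
                    xin[:, 0] * VGG_SD[0] + VGG_MEAN[0], 0.0, 1.0)))
                lg = loss_gen2(dis, yfn, y3.detach())
                opt_gen.step(nn.compute_grads(lg, gen.parameters()))
                update_log.append("gen")
            if (len(running) == running.maxlen
                    and float(np.mean(running)) < schedule.phase_c_margin_stop):
                crossed = True
                break
        margin = float(np.mean(running))
        records.append({"phase": "C", "epoch": epoch, "loss_gen1": np.nan,
                        "margin": margin})
        logger.info("GAN %s phase C epoch %d running margin %.4f",
                    direction, epoch, margin)
        if crossed:
            break
    else:
        logger.warning("phase C hit its epoch cap before margin < %.3g",
                       schedule.phase_c_margin_stop)

    gen.eval()
    return AdversarialGenerator(model=gen, direction=direction,
                                schedule=schedule,
                                log=pd.DataFrame(records),
                                update_log=update_log,
                                phase_b_frozen_delta=phase_b_delta)


def _three_channel_aug(images: list[PhantomImage], rng) -> np.ndarray:
    return np.stack([normalize_for_model(augment(img.pixels, rng), 3)
                     for img in images])


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def generate_adversarial(generator: AdversarialGenerator,
                         image: PhantomImage) -> AdversarialPair:
    """Produce the label-flipped fake counterpart of one real image."""
    expected = "positive" if generator.direction == "remove_lesion" else "negative"
    if image.label != expected:
        raise ValueError(
            f"{generator.direction} generator expects {expected} images, "
            f"got {image.label}")
    gen = generator.model
    was_training = gen.training
    gen.eval()
    try:
        with ad.default_dtype(gen.parameter_dtype()):
            xin = normalize_for_model(image.pixels, 1)[None]
            out01 = gen(Tensor(xin)).data[0, 0]
    finally:
        gen.train(was_training)
    fake_pixels = unit_to_u16(np.asarray(out01, dtype=np.float64))
    flipped = "negative" if image.label == "positive" else "positive"
    fake = dataclasses.replace(
        image, pixels=fake_pixels, label=flipped, realness="fake")
    return AdversarialPair(real=image, fake=fake, direction=generator.direction)
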