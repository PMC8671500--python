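"""Binary CAD classifier: architecture, composite loss, staged training.

The classifier maps a 3-channel normalized mammogram to softmax
probabilities (negative, positive). It is a convolutional feature extractor
("Vnet") followed by a head ("Fnet") with GroupNorm, LeakyReLU(0.2),
Dropout(0.2), a 2x2/stride-1 average pool, global max pooling (lesions are
small, so the firing element should be magnified rather than averaged) and a
fully connected stack ending in a 2-class softmax.

Training minimizes the composite loss

    Loss_cls = FL(p_p) + FL(p_n) + GP(g_p, g_n)

where FL is the focal loss with focusing parameter gamma over the N
correct-class probabilities of the positive (p_p) and negative (p_n) half of
the batch, and GP penalizes the L2 norm (raised to power ``o``, scaled by
``k/2N``) of the input-pixel gradient of the scalar pre-softmax
positive-class score — a double-backprop regularizer that smooths the
decision function. Optimization is Adam (beta1=0.5, beta2=0.9) in two
stages: first the head only (the backbone keeps its initialization), then
head and backbone jointly at separate learning rates.

Two backbone realizations are provided. "Full mode" describes the first 20
layers of VGG11 plus a head conv stack whose analytic receptive field is
exactly 406 pixels. "Desk mode" is a scaled-down stack for 128x104 phantoms
whose receptive field (76 px) still covers the configured lesion extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .phantom import DatasetSplit, PhantomImage, augment, normalize_for_model

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# architecture specs and the receptive-field calculator
# ---------------------------------------------------------------------------

@dataclass
class BackboneSpec:
    """Layer table of the conv stack up to (not including) global pooling.

    Each entry is ``("conv"|"pool", kernel, stride, padding)``. The table is
    what the receptive-field calculator consumes; ``channels`` drives the
    concrete desk-mode network construction.
    """
    mode: str                                  # "full" | "desk"
    layers: list[tuple[str, int, int, int]]
    channels: list[int] = field(default_factory=list)
    target_receptive_field: int = 0

    def validate(self):
        rf = receptive_field(self.layers)
        if rf != self.target_receptive_field:
            raise ValueError(
                f"configured stack has receptive field {rf}, "
                f"target is {self.target_receptive_field}"
            )
        return self


def receptive_field(layers: list[tuple[str, int, int, int]]) -> int:
    """Analytic receptive field: r += (kernel-1)*jump; jump *= stride."""
    r, jump = 1, 1
    for layer in layers:
        kind, kernel, stride = layer[0], layer[1], layer[2]
        if kind not in ("conv", "pool"):
            raise ValueError(f"unsupported layer kind: {kind}")
        r += (kernel - 1) * jump
        jump *= stride
    return r


def full_backbone() -> BackboneSpec:
    """First 20 VGG11 layers + head convs reaching receptive field 406."""
    vgg11_20 = [
        ("conv", 3, 1, 1), ("pool", 2, 2, 0),
        ("conv", 3, 1, 1), ("pool", 2, 2, 0),
        ("conv", 3, 1, 1), ("conv", 3, 1, 1), ("pool", 2, 2, 0),
        ("conv", 3, 1, 1), ("conv", 3, 1, 1), ("pool", 2, 2, 0),
        ("conv", 3, 1, 1), ("conv", 3, 1, 1),
    ]
    head = [("pool", 2, 1, 0)] + [("conv", 3, 1, 1)] * 8
    return BackboneSpec(
        mode="full",
        layers=vgg11_20 + head,
        channels=[64, 128, 256, 256, 512, 512, 512, 512],
        target_receptive_field=406,
    ).validate()


def desk_backbone() -> BackboneSpec:
    """Reduced stack for 128x104 phantoms; receptive field 76 px covers the
    default lesion extent (radius <= 12 px plus spicules). The stack pools
    first so most convolutions run at half resolution."""
    layers = [
        ("pool", 2, 2, 0), ("conv", 3, 1, 1),
        ("pool", 2, 2, 0), ("conv", 3, 1, 1),
        ("pool", 2, 2, 0), ("conv", 3, 1, 1), ("conv", 3, 1, 1),
        # head portion
        ("conv", 3, 1, 1), ("pool", 2, 1, 0),
    ]
    return BackboneSpec(
        mode="desk", layers=layers,
        channels=[16, 32, 64, 64],
        target_receptive_field=76,
    ).validate()


@dataclass
class ClassifierLossParams:
    gamma: float = 2.0    # focal-loss focusing parameter
    k: float = 10.0       # gradient-penalty coefficient
    o: float = 4.0        # gradient-penalty power
    n_per_class: int = 4  # N: images per class per batch

    def validate(self):
        if self.gamma < 0 or self.k <= 0 or self.o < 1 or self.n_per_class < 1:
            raise ValueError("invalid classifier loss parameters")
        return self


@dataclass
class OptimizerSpec:
    beta1: float = 0.5
    beta2: float = 0.9
    lr_head: float = 1e-4
    lr_backbone: float = 1e-5
    head_only_epochs: int = 41
    total_epochs: int = 60

    def validate(self):
        if self.lr_head <= 0 or self.lr_backbone <= 0:
            raise ValueError("learning rates must be positive")
        return self


def desk_optimizer() -> OptimizerSpec:
    """Training schedule for the randomly initialized desk backbone.

    The head-only stage exists to protect a *pretrained* backbone; the desk
    backbone is random, so the stage is brief and both parts then train at
    the same rate (a tiny backbone rate would leave random features frozen).
    """
    return OptimizerSpec(lr_head=3e-4, lr_backbone=3e-4,
                         head_only_epochs=2, total_epochs=100)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class CadClassifier(nn.Module):
    """Desk-mode concrete network: Vnet feature extractor + Fnet head."""

    def __init__(self, spec: BackboneSpec | None = None, seed: int = 0,
                 head_outputs: int = 2):
        super().__init__()
        spec = spec or desk_backbone()
        if spec.mode != "desk":
            raise ValueError(
                "only the desk-mode stack is instantiated as a live network; "
                "full mode is an architecture table for the RF calculator"
            )
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCAD]))
        c1, c2, c3, c4 = spec.channels
        self.vnet = nn.Sequential(
            nn.AvgPool2d(2, 2),
            nn.Conv2d(3, c1, 3, padding=1, rng=rng), nn.LeakyReLU(0.2),
            nn.AvgPool2d(2, 2),
            nn.Conv2d(c1, c2, 3, padding=1, rng=rng), nn.LeakyReLU(0.2),
            nn.AvgPool2d(2, 2),
            nn.Conv2d(c2, c3, 3, padding=1, rng=rng), nn.LeakyReLU(0.2),
            nn.Conv2d(c3, c4, 3, padding=1, rng=rng), nn.LeakyReLU(0.2),
        )
        drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0]))
        # 8 groups: group size 8, the desk-scale analogue of 32 groups on
        # 512 channels (keeps within-group statistics meaningful)
        self.fnet_conv = nn.Sequential(
            nn.GroupNorm(min(8, c4), c4),
            nn.Conv2d(c4, c4, 3, padding=1, rng=rng), nn.LeakyReLU(0.2),
            nn.Dropout(0.2, rng=drop_rng),
            nn.AvgPool2d(2, 1),
        )
        self.fnet_fc = nn.Sequential(
            nn.Linear(c4, 16, rng=rng), nn.LeakyReLU(0.2),
            nn.Dropout(0.2, rng=drop_rng),
            nn.Linear(16, head_outputs, rng=rng),
        )

    # -- forward pieces ----------------------------------------------------
    def logits(self, x: Tensor) -> Tensor:
        feat = self.fnet_conv(self.vnet(x))
        pooled = ad.global_max_pool(feat)
        return self.fnet_fc(pooled)

    def forward(self, x: Tensor) -> Tensor:
        return ad.softmax(self.logits(x), axis=1)

    def score_positive(self, x: Tensor) -> Tensor:
        """Scalar pre-softmax positive-class score per sample, shape (B,)."""
        lg = self.logits(x)
        return ad.reshape(ad.slice_axis(lg, 1, 1, 2), (lg.shape[0],))

    # -- parameter groups ---------------------------------------------------
    def backbone_parameters(self) -> list[Tensor]:
        return self.vnet.parameters()

    def head_parameters(self) -> list[Tensor]:
        return self.fnet_conv.parameters() + self.fnet_fc.parameters()


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------

_CLAMP_EPS = 1e-7


def _clamp_min(p: Tensor, eps: float) -> Tensor:
    low = p.data < eps
    if low.any():
        logger.warning("focal loss: clamped %d probabilities below %.1e",
                       int(low.sum()), eps)
        return p * Tensor(np.where(low, 0.0, 1.0)) + Tensor(np.where(low, eps, 0.0))
    return p


def focal_loss(probs, gamma: float = 2.0) -> Tensor:
    """Mean over the batch of -(1-p_j)^gamma * ln(p_j).

    ``probs`` are the correct-class probabilities; values below 1e-7 are
    clamped (and logged) for numerical safety.
    """
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=float))
    if (p.data < 0).any() or (p.data > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    p = _clamp_min(p, _CLAMP_EPS)
    n = p.size
    return ((Tensor(1.0) - p) ** gamma * (-ad.log(p))).sum() * (1.0 / n)


def _grad_norm_pow_sum(score_fn, batch, o: float) -> Tensor:
    """Sum over the batch of ||d score_j / d x_j||_2^o (differentiable)."""
    x = Tensor(batch.data if isinstance(batch, Tensor) else np.asarray(batch, dtype=float))
    score = score_fn(x)
    g = ad.grad(score.sum(), x)
    axes = tuple(range(1, g.ndim))
    sq = (g ** 2).sum(axis=axes)          # (B,) squared norms
    return (sq ** (o / 2.0)).sum()


def input_gradient_penalty(score_fn, batch_a, batch_b,
                           k: float = 10.0, o: float = 4.0) -> Tensor:
    """k/(2N) * sum_j (||grad_j^a||^o + ||grad_j^b||^o).

    ``score_fn`` maps an image batch Tensor (B, C, H, W) to per-sample scalar
    scores (B,); the gradient is taken w.r.t. the input pixels. The result
    stays connected to the model parameters, so its own gradient trains the
    model (double backprop).
    """
    na = (batch_a.shape[0] if isinstance(batch_a, Tensor)
          else np.asarray(batch_a).shape[0])
    nb = (batch_b.shape[0] if isinstance(batch_b, Tensor)
          else np.asarray(batch_b).shape[0])
    if na != nb:
        raise ValueError("batches must have equal size N")
    total = _grad_norm_pow_sum(score_fn, batch_a, o) + \
        _grad_norm_pow_sum(score_fn, batch_b, o)
    return total * (k / (2.0 * na))


def classifier_loss(model: CadClassifier, pos_batch, neg_batch,
                    params: ClassifierLossParams) -> tuple[Tensor, dict]:
    """Composite loss FL(p_p) + FL(p_n) + GP(g_p, g_n) on one balanced batch.

    ``pos_batch``/``neg_batch`` are normalized image arrays (N, 3, H, W).
    Returns the scalar loss tensor and a dict of the (detached) components.
    """
    pos_batch = np.asarray(pos_batch, dtype=float)
    neg_batch = np.asarray(neg_batch, dtype=float)
    n = pos_batch.shape[0]
    if neg_batch.shape[0] != n:
        raise ValueError("positive and negative batches must both hold N images")
    # one shared forward over the combined batch: probabilities, positive-class
    # scores and the input gradient all come from the same graph
    x = Tensor(np.concatenate([pos_batch, neg_batch]))
    logits = model.logits(x)
    probs = ad.softmax(logits, axis=1)
    prob_p = ad.reshape(ad.slice_axis(ad.slice_axis(probs, 0, 0, n), 1, 1, 2), (n,))
    prob_n = ad.reshape(ad.slice_axis(ad.slice_axis(probs, 0, n, 2 * n), 1, 0, 1), (n,))
    fl_p = focal_loss(prob_p, params.gamma)
    fl_n = focal_loss(prob_n, params.gamma)
    score = ad.reshape(ad.slice_axis(logits, 1, 1, 2), (2 * n,))
    g = ad.grad(score.sum(), x)
    sq = (g ** 2).sum(axis=tuple(range(1, g.ndim)))
    gp = (sq ** (params.o / 2.0)).sum() * (params.k / (2.0 * n))
    loss = fl_p + fl_n + gp
    parts = {"focal_pos": fl_p.item(), "focal_neg": fl_n.item(),
             "gradient_penalty": gp.item()}
    return loss, parts


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    model: CadClassifier
    spec: BackboneSpec
    log: pd.DataFrame
    best_epoch: int
    best_val_auc: float


def _normalized_batch(images: list[PhantomImage], rng=None) -> np.ndarray:
    arrs = []
    for img in images:
        pixels = img.pixels if rng is None else augment(img.pixels, rng)
        arrs.append(normalize_for_model(pixels, 3))
    return np.stack(arrs)


def predict_prob(model: CadClassifier, image) -> float:
    """Positive-class probability for one image (PhantomImage or uint16 array)."""
    pixels = image.pixels if isinstance(image, PhantomImage) else image
    return float(predict_prob_batch(model, [pixels])[0])


def predict_prob_batch(model: CadClassifier, images) -> np.ndarray:
    was_training = model.training
    model.eval()
    try:
        arrs = [normalize_for_model(
            img.pixels if isinstance(img, PhantomImage) else img, 3)
            for img in images]
        with ad.default_dtype(model.parameter_dtype()):
            probs = model(Tensor(np.stack(arrs))).data[:, 1]
    finally:
        model.train(was_training)
    return probs.astype(np.float64)


def _val_auc(model: CadClassifier, images: list[PhantomImage],
             batch: int = 16) -> float:
    labels = [1 if im.label == "positive" else 0 for im in images]
    scores = []
    for i in range(0, len(images), batch):
        scores.extend(predict_prob_batch(model, images[i:i + batch]))
    return float(roc_auc_score(labels, scores))


def train_classifier(split: DatasetSplit,
                     spec: BackboneSpec | None = None,
                     opt: OptimizerSpec | None = None,
                     loss_params: ClassifierLossParams | None = None,
                     seed: int = 0,
                     model: CadClassifier | None = None,
                     dtype: str = "float32",
                     select: str = "best_val") -> TrainedClassifier:
    """Two-stage training; returns the model maximizing validation AUC.

    Stage 1 updates the head only for ``opt.head_only_epochs`` so the
    backbone keeps its initialization; stage 2 trains head and backbone
    jointly at their respective learning rates. Every batch holds N
    augmented positives and N augmented negatives. Training runs in
    ``dtype`` working precision (float32 by default).
    """
    spec = spec or desk_backbone()
    opt = (opt or OptimizerSpec()).validate()
    loss_params = (loss_params or ClassifierLossParams()).validate()

    pos = [im for im in split.train if im.label == "positive"]
    neg = [im for im in split.train if im.label == "negative"]
    if not pos or not neg:
        raise ValueError("training data must contain both classes")
    if not split.val:
        raise ValueError("validation partition is empty")
    if len({im.label for im in split.val}) < 2:
        raise ValueError("validation partition needs both classes for AUC")

    dt = model.parameter_dtype() if model is not None else np.dtype(dtype)
    with ad.default_dtype(dt):
        return _train_classifier_inner(split, spec, opt, loss_params, seed,
                                       model, pos, neg, select)


def _train_classifier_inner(split, spec, opt, loss_params, seed, model,
                            pos, neg, select) -> TrainedClassifier:
    model = model or CadClassifier(spec, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7EA1]))

    n = loss_params.n_per_class
    head_group = [{"params": model.head_parameters(), "lr": opt.lr_head}]
    both_groups = head_group + [
        {"params": model.backbone_parameters(), "lr": opt.lr_backbone}]
    optimizer = nn.Adam(head_group, beta1=opt.beta1, beta2=opt.beta2)

    records = []
    best_state, best_auc, best_epoch = model.state_dict(), -np.inf, -1
    for epoch in range(opt.total_epochs):
        if epoch == opt.head_only_epochs:
            optimizer = nn.Adam(both_groups, beta1=opt.beta1, beta2=opt.beta2)
        stage = 1 if epoch < opt.head_only_epochs else 2
        trainable = (model.head_parameters() if stage == 1
                     else model.head_parameters() + model.backbone_parameters())
        model.train()
        pos_order = rng.permutation(len(pos))
        neg_order = rng.permutation(len(neg))
        steps = max(len(pos) // n, 1)
        epoch_loss = 0.0
        for step in range(steps):
            pick_p = [pos[i] for i in pos_order[(step * n) % len(pos):][:n]]
            while len(pick_p) < n:
                pick_p.append(pos[rng.integers(len(pos))])
            pick_n = [neg[i] for i in neg_order[(step * n) % len(neg):][:n]]
            while len(pick_n) < n:
                pick_n.append(neg[rng.integers(len(neg))])
            batch_p = _normalized_batch(pick_p, rng)
            batch_n = _normalized_batch(pick_n, rng)
            loss, _ = classifier_loss(model, batch_p, batch_n, loss_params)
            grads = nn.compute_grads(loss, trainable)
            optimizer.step(grads)
            epoch_loss += loss.item()
        val_auc = _val_auc(model, split.val)
        records.append({"epoch": epoch, "stage": stage,
                        "loss": epoch_loss / steps, "val_auc": val_auc})
        logger.info("epoch %d stage %d loss %.4f val AUC %.3f",
                    epoch, stage, epoch_loss / steps, val_auc)
        if val_auc > best_auc:
            best_auc, best_epoch, best_state = val_auc, epoch, model.state_dict()
    if select == "best_val":
        model.load_state_dict(best_state)
    model.eval()
    return TrainedClassifier(model=model, spec=spec,
                             log=pd.DataFrame(records),
                             best_epoch=best_epoch, best_val_auc=best_auc)
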