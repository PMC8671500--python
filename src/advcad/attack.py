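"""Attack evaluation: AUC, threshold accuracy, fool rates, education panels.

The protocol mirrors the study's AI-model evaluation. The classifier scores
every real test image and its GAN-generated counterpart. The real set is
scored against the true labels; the adversarial set against the *flipped*
labels (a negative-looking fake made from a positive is labeled negative,
and vice versa). Accuracy uses a fixed probability threshold of 0.5. The
fool rate of a class is computed over the real images of that class that the
classifier got right: the fraction whose counterfeit is classified as the
flipped label. The pooled rate merges both classes' correct cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "AttackRecord",
    "ClassReport",
    "FoolRateReport",
    "auc",
    "classify_at_threshold",
    "fool_rate_report",
    "pooled_fool_rate",
    "education_panel",
]


@dataclass
class AttackRecord:
    image_id: str
    true_label: str                  # "positive" | "negative"
    prob_real: float                 # classifier output on the real image
    prob_fake: float                 # classifier output on the counterfeit

    def __post_init__(self):
        if self.true_label not in ("positive", "negative"):
            raise ValueError("true_label must be positive or negative")
        for p in (self.prob_real, self.prob_fake):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def flipped_label(self) -> str:
        return "negative" if self.true_label == "positive" else "positive"


@dataclass
class ClassReport:
    n_real: int
    n_correct: int
    n_fooled: int

    @property
    def pct_correct(self) -> float | None:
        return None if self.n_real == 0 else round(100.0 * self.n_correct / self.n_real, 1)

    @property
    def pct_fooled(self) -> float | None:
        """Undefined (None) when no real image of the class was classified
        correctly."""
        return None if self.n_correct == 0 else round(100.0 * self.n_fooled / self.n_correct, 1)


@dataclass
class FoolRateReport:
    auc_real: float
    auc_adversarial: float           # adversarial images scored on flipped labels
    positive: ClassReport = field(default_factory=lambda: ClassReport(0, 0, 0))
    negative: ClassReport = field(default_factory=lambda: ClassReport(0, 0, 0))

    @property
    def n_correct_total(self) -> int:
        return self.positive.n_correct + self.negative.n_correct

    @property
    def n_fooled_total(self) -> int:
        return self.positive.n_fooled + self.negative.n_fooled

    @property
    def pct_fooled_pooled(self) -> float | None:
        if self.n_correct_total == 0:
            return None
        return round(100.0 * self.n_fooled_total / self.n_correct_total, 1)

    def to_dict(self) -> dict:
        return {
            "auc_real": self.auc_real,
            "auc_adversarial_flipped_labels": self.auc_adversarial,
            "positive": {"n_real": self.positive.n_real,
                         "n_correct": self.positive.n_correct,
                         "pct_correct": self.positive.pct_correct,
                         "n_fooled": self.positive.n_fooled,
                         "pct_fooled": self.positive.pct_fooled},
            "negative": {"n_real": self.negative.n_real,
                         "n_correct": self.negative.n_correct,
                         "pct_correct": self.negative.pct_correct,
                         "n_fooled": self.negative.n_fooled,
                         "pct_fooled": self.negative.pct_fooled},
            "pooled": {"n_fooled_total": self.n_fooled_total,
                       "n_correct_total": self.n_correct_total,
                       "pct_fooled_pooled": self.pct_fooled_pooled},
        }

    def to_text(self) -> str:
        def fmt(v):
            return "--" if v is None else f"{v}%"
        lines = [
            f"AUC real images: {self.auc_real:.2f}   "
            f"AUC adversarial (flipped labels): {self.auc_adversarial:.2f}",
            "class     correct real            fooled among correct",
            f"positive  {fmt(self.positive.pct_correct)} "
            f"({self.positive.n_correct}/{self.positive.n_real})"
            f"    {fmt(self.positive.pct_fooled)} "
            f"({self.positive.n_fooled}/{self.positive.n_correct})",
            f"negative  {fmt(self.negative.pct_correct)} "
            f"({self.negative.n_correct}/{self.negative.n_real})"
            f"    {fmt(self.negative.pct_fooled)} "
            f"({self.negative.n_fooled}/{self.negative.n_correct})",
            f"pooled fool rate: {fmt(self.pct_fooled_pooled)} "
            f"({self.n_fooled_total}/{self.n_correct_total})",
        ]
        return "\n".join(lines)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def classify_at_threshold(prob: float, threshold: float = 0.5) -> str:
    """Positive iff prob strictly exceeds the threshold (tie -> negative)."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must lie in [0, 1]")
    return "positive" if prob > threshold else "negative"


def pooled_fool_rate(pos_fooled: int, pos_correct: int,
                     neg_fooled: int, neg_correct: int) -> float:
    """100 * (fooled_p + fooled_n) / (correct_p + correct_n), one decimal."""
    for fooled, correct in ((pos_fooled, pos_correct), (neg_fooled, neg_correct)):
        if fooled < 0 or correct < 0 or fooled > correct:
            raise ValueError("need 0 <= fooled <= correct in each class")
    total_correct = pos_correct + neg_correct
    if total_correct == 0:
        raise ValueError("no correctly classified cases: pooled rate undefined")
    return round(100.0 * (pos_fooled + neg_fooled) / total_correct, 1)


def fool_rate_report(records: list[AttackRecord],
                     threshold: float = 0.5) -> FoolRateReport:
    """Aggregate attack records into the study's table layout.

    For each class: *correct* counts real images classified as their true
    label; *fooled* counts, among those, the counterfeits classified as the
    flipped label. AUCs: real probabilities vs. true labels, and counterfeit
    probabilities vs. flipped labels.
    """
    if not records:
        raise ValueError("no attack records")
    reports = {}
    for cls in ("positive", "negative"):
        of_class = [r for r in records if r.true_label == cls]
        correct = [r for r in of_class
                   if classify_at_threshold(r.prob_real, threshold) == cls]
        fooled = [r for r in correct
                  if classify_at_threshold(r.prob_fake, threshold) == r.flipped_label]
        reports[cls] = ClassReport(n_real=len(of_class), n_correct=len(correct),
                                   n_fooled=len(fooled))
    true01 = [1 if r.true_label == "positive" else 0 for r in records]
    flipped01 = [1 if r.flipped_label == "positive" else 0 for r in records]
    return FoolRateReport(
        auc_real=auc([r.prob_real for r in records], true01),
        auc_adversarial=auc([r.prob_fake for r in records], flipped01),
        positive=reports["positive"],
        negative=reports["negative"],
    )


# ---------------------------------------------------------------------------
# education panels (real | fake | signed difference)
# ---------------------------------------------------------------------------

def education_panel(real: np.ndarray, fake: np.ndarray,
                    separator: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Side-by-side triptych of real, fake, and their signed difference.

    Returns ``(panel_u8, difference)``: an 8-bit displayable panel of width
    ``3*W + 2*separator`` and the lossless signed difference (real - fake,
    float64). The difference is rendered with a symmetric window about zero
    so equal positive/negative changes get equal contrast.
    """
    real = np.asarray(real)
    fake = np.asarray(fake)
    if real.shape != fake.shape:
        raise ValueError("real and fake must have the same dimensions")
    diff = real.astype(np.float64) - fake.astype(np.float64)

    def to_u8(img):
        img = img.astype(np.float64)
        lo, hi = img.min(), img.max()
        if hi == lo:
            return np.zeros(img.shape, dtype=np.uint8)
        return np.round(255 * (img - lo) / (hi - lo)).astype(np.uint8)

    amp = np.max(np.abs(diff))
    diff_u8 = (np.full(diff.shape, 127, dtype=np.uint8) if amp == 0
               else np.round(127.5 + 127.5 * diff / amp).clip(0, 255).astype(np.uint8))
    h, w = real.shape
    sep = np.zeros((h, separator), dtype=np.uint8)
    panel = np.concatenate(
        [to_u8(real), sep, to_u8(fake), sep, diff_u8], axis=1)
    return panel, diff


def save_education_panel(real: np.ndarray, fake: np.ndarray,
                         out_png: str | Path, out_diff_tif: str | Path | None = None):
    import imageio.v3 as iio
    import tifffile

    panel, diff = education_panel(real, fake)
    iio.imwrite(Path(out_png), panel)
    if out_diff_tif is not None:
        tifffile.imwrite(Path(out_diff_tif), diff.astype(np.float32))
    return panel, diff
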