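"""Synthetic phantom-mammogram cohort and image preprocessing.

The study needs a cohort with the structure of a screening-mammography
dataset: mostly negative patients, a minority with a malignant mass, up to
four views per patient (CC and MLO of each breast), and a patient-level
train/validation/test split. No clinical images are used anywhere; this
module fabricates 16-bit grayscale phantoms instead:

* the *background* is multi-scale correlated Gaussian noise inside an
  elliptical breast mask on a zero background, emulating fibroglandular
  texture so the generative model has structure to modify;
* a *lesion* is an additive, radially decaying bright blob (Gaussian profile,
  peak amplitude a configurable fraction of the 16-bit dynamic range) plus a
  few linear spicules, emulating mass-type lesions.

Positive patients contribute only views of the cancer-affected breast;
negative patients contribute both breasts. The same module houses the
preprocessing the pipeline applies to every image: ratio-preserved bicubic
resizing with zero padding, training-time affine augmentation (vertical flip,
rotation +-45 deg, scaling 0.5-2, shearing +-45 deg, bilinear interpolation,
zero padding), and normalization to the VGG11 convention.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import transform as sktransform

U16_MAX = 65535

# torchvision / VGG11 ImageNet normalization constants
VGG_MEAN = np.array([0.485, 0.456, 0.406])
VGG_SD = np.array([0.229, 0.224, 0.225])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class BackgroundTexture:
    correlation_length: float = 6.0   # px
    intensity_mean: float = 22000.0   # 16-bit counts
    intensity_sd: float = 3000.0


@dataclass
class LesionParams:
    radius_range: tuple[float, float] = (6.0, 12.0)        # px
    peak_contrast_range: tuple[float, float] = (0.16, 0.32)  # fraction of range
    spicule_count_range: tuple[int, int] = (4, 10)
    spicule_length_range: tuple[float, float] = (4.0, 12.0)  # px


@dataclass
class PhantomConfig:
    n_patients: int = 100
    positive_fraction: float = 0.285   # cohort structure: 366 of 1284 patients
    views_per_patient: int = 4
    image_height: int = 128
    image_width: int = 104
    background_texture: BackgroundTexture = field(default_factory=BackgroundTexture)
    lesion: LesionParams = field(default_factory=LesionParams)
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def validate(self) -> "PhantomConfig":
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("pixel dimensions must be positive")
        if not 1 <= self.views_per_patient <= 4:
            raise ValueError("views_per_patient must be in 1..4")
        return self


@dataclass
class LesionSpec:
    center: tuple[float, float]      # (row, col)
    radius: float
    peak_contrast: float
    n_spicules: int
    spicule_length: float


@dataclass
class PhantomImage:
    pixels: np.ndarray               # uint16 (H, W)
    label: str                       # "positive" | "negative"
    realness: str                    # "real" | "fake"
    patient_id: str
    view: str                        # "CC" | "MLO"
    laterality: str                  # "L" | "R"
    lesion_specs: list[LesionSpec] = field(default_factory=list)

    @property
    def image_id(self) -> str:
        return f"{self.patient_id}_{self.laterality}{self.view}"


@dataclass
class DatasetSplit:
    train: list[PhantomImage]
    val: list[PhantomImage]
    test: list[PhantomImage]
    assignment: dict[str, str]       # patient_id -> partition

    def partition(self, name: str) -> list[PhantomImage]:
        return getattr(self, name)


# ---------------------------------------------------------------------------
# background and lesion synthesis
# ---------------------------------------------------------------------------

def breast_mask(height: int, width: int) -> np.ndarray:
    """Elliptical support of the phantom breast on a zero background."""
    rr, cc = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ay, ax = 0.46 * height, 0.44 * width
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def synth_background(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Correlated multi-scale Gaussian texture inside the breast mask (uint16)."""
    h, w = config.image_height, config.image_width
    tex = config.background_texture
    base = rng.normal(size=(h, w))
    field_sum = np.zeros((h, w))
    # three octaves around the configured correlation length
    for factor, weight in ((0.5, 0.4), (1.0, 1.0), (2.0, 0.6)):
        smooth = ndimage.gaussian_filter(base, tex.correlation_length * factor)
        std = smooth.std()
        if std > 0:
            field_sum += weight * smooth / std
        base = rng.normal(size=(h, w))
    field_sum /= np.sqrt(0.4 ** 2 + 1.0 + 0.6 ** 2)
    img = tex.intensity_mean + tex.intensity_sd * field_sum
    img *= breast_mask(h, w)
    return np.clip(np.round(img), 0, U16_MAX).astype(np.uint16)


def _lesion_field(shape: tuple[int, int], spec: LesionSpec,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Additive lesion intensity field: Gaussian blob + linear spicules."""
    h, w = shape
    cy, cx = spec.center
    amplitude = spec.peak_contrast * U16_MAX
    rr, cc = np.mgrid[0:h, 0:w]
    r2 = (rr - cy) ** 2 + (cc - cx) ** 2
    sigma = spec.radius / 2.0
    blob = amplitude * np.exp(-r2 / (2.0 * sigma ** 2))
    out = blob
    if spec.n_spicules > 0:
        rng = rng or np.random.default_rng(0)
        angles = rng.uniform(0.0, 2 * np.pi, spec.n_spicules)
        spic = np.zeros((h, w))
        n_steps = max(int(np.ceil(spec.spicule_length)) * 2, 2)
        for theta in angles:
            # ridge from the disk edge outward, amplitude tapering to zero
            t = np.linspace(0.0, 1.0, n_steps)
            rad = spec.radius * 0.7 + t * spec.spicule_length
            ys = np.clip(np.round(cy + rad * np.sin(theta)).astype(int), 0, h - 1)
            xs = np.clip(np.round(cx + rad * np.cos(theta)).astype(int), 0, w - 1)
            amp = 0.5 * amplitude * (1.0 - t)
            np.maximum.at(spic, (ys, xs), amp)
        spic = ndimage.gaussian_filter(spic, 0.7)
        out = np.maximum(blob, spic)
    return out


def insert_lesion(image: PhantomImage, spec: LesionSpec,
                  rng: np.random.Generator | None = None) -> PhantomImage:
    """Return a new image with the lesion added; the input is untouched."""
    h, w = image.pixels.shape
    cy, cx = spec.center
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("lesion center outside image bounds")
    if (cy - spec.radius < 0 or cy + spec.radius >= h
            or cx - spec.radius < 0 or cx + spec.radius >= w):
        raise ValueError("lesion disk extends outside image bounds")
    added = _lesion_field((h, w), spec, rng)
    pixels = np.clip(np.round(image.pixels.astype(np.float64) + added), 0, U16_MAX)
    return dataclasses.replace(
        image,
        pixels=pixels.astype(np.uint16),
        label="positive",
        lesion_specs=image.lesion_specs + [spec],
    )


def _sample_lesion_spec(config: PhantomConfig, rng: np.random.Generator) -> LesionSpec:
    les = config.lesion
    h, w = config.image_height, config.image_width
    radius = rng.uniform(*les.radius_range)
    length = rng.uniform(*les.spicule_length_range)
    margin = radius + length + 2.0
    mask = breast_mask(h, w)
    for _ in range(1000):
        cy = rng.uniform(margin, h - 1 - margin)
        cx = rng.uniform(margin, w - 1 - margin)
        ic, jc = int(round(cy)), int(round(cx))
        box = mask[max(ic - int(margin), 0):ic + int(margin) + 1,
                   max(jc - int(margin), 0):jc + int(margin) + 1]
        if box.size and box.all():
            break
    else:  # pragma: no cover - geometry always admits a center at default sizes
        raise RuntimeError("could not place lesion inside the breast mask")
    return LesionSpec(
        center=(cy, cx),
        radius=radius,
        peak_contrast=rng.uniform(*les.peak_contrast_range),
        n_spicules=int(rng.integers(les.spicule_count_range[0],
                                    les.spicule_count_range[1] + 1)),
        spicule_length=length,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _image_rng(master_seed: int, patient_index: int, view_index: int) -> np.random.Generator:
    """Counter-based per-image stream: any single image is regenerable."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, patient_index, view_index])
    )


_NEGATIVE_VIEWS = [("L", "CC"), ("L", "MLO"), ("R", "CC"), ("R", "MLO")]


def generate_cohort(config: PhantomConfig) -> DatasetSplit:
    """Generate the phantom cohort and its patient-level split.

    Deterministic given ``config.seed``. Positive patients contribute only
    views of the affected breast (at most two: CC and MLO); negative patients
    contribute both breasts up to ``views_per_patient`` images. The split
    honors the configured fractions per class by rounding down, with the
    remainder assigned to train.
    """
    config.validate()
    n_pos = int(round(config.n_patients * config.positive_fraction))
    n_neg = config.n_patients - n_pos
    if n_pos < 3 or n_neg < 3:
        raise ValueError(
            "n_patients too small to populate train/val/test in both classes"
        )

    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    patients = [(f"P{i:04d}", "positive" if i < n_pos else "negative")
                for i in range(config.n_patients)]

    assignment = _split_patients(patients, config.split_fractions, master)

    partitions: dict[str, list[PhantomImage]] = {"train": [], "val": [], "test": []}
    for idx, (pid, label) in enumerate(patients):
        meta_rng = _image_rng(config.seed, idx, 999)
        if label == "positive":
            side = "L" if meta_rng.random() < 0.5 else "R"
            views = [(side, "CC"), (side, "MLO")][: min(config.views_per_patient, 2)]
        else:
            views = _NEGATIVE_VIEWS[: config.views_per_patient]
        for v_idx, (lat, view) in enumerate(views):
            rng = _image_rng(config.seed, idx, v_idx)
            background = synth_background(config, rng)
            img = PhantomImage(
                pixels=background, label="negative", realness="real",
                patient_id=pid, view=view, laterality=lat,
            )
            if label == "positive":
                spec = _sample_lesion_spec(config, rng)
                img = insert_lesion(img, spec, rng)
            partitions[assignment[pid]].append(img)
    return DatasetSplit(
        train=partitions["train"], val=partitions["val"], test=partitions["test"],
        assignment=assignment,
    )


def _split_patients(patients, fractions, rng) -> dict[str, str]:
    """Patient-level stratified split; floor counts, remainder to train."""
    assignment: dict[str, str] = {}
    for cls in ("positive", "negative"):
        ids = [pid for pid, label in patients if label == cls]
        order = rng.permutation(len(ids))
        n = len(ids)
        n_val = int(n * fractions[1])
        n_test = int(n * fractions[2])
        n_train = n - n_val - n_test
        for rank, i in enumerate(order):
            if rank < n_train:
                part = "train"
            elif rank < n_train + n_val:
                part = "val"
            else:
                part = "test"
            assignment[ids[i]] = part
    return assignment


# ---------------------------------------------------------------------------
# lesion contrast statistic (cohort learnability check)
# ---------------------------------------------------------------------------

def lesion_disk_mask(image: PhantomImage, specs: list[LesionSpec] | None = None) -> np.ndarray:
    specs = image.lesion_specs if specs is None else specs
    h, w = image.pixels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for spec in specs:
        cy, cx = spec.center
        mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= spec.radius ** 2
    return mask


def contrast_statistic(image: PhantomImage,
                       probe_spec: LesionSpec | None = None) -> float:
    """Mean lesion-disk intensity minus mean of the lesion-free background.

    For negatives, a probe disk (where a lesion *would* be) must be supplied
    so the statistic is computed over comparable regions.
    """
    specs = image.lesion_specs if image.lesion_specs else [probe_spec]
    if specs[0] is None:
        raise ValueError("negative image needs a probe_spec")
    disk = lesion_disk_mask(image, specs)
    support = breast_mask(*image.pixels.shape) & ~disk
    pixels = image.pixels.astype(np.float64)
    return float(pixels[disk].mean() - pixels[support].mean())


# ---------------------------------------------------------------------------
# preprocessing operators
# ---------------------------------------------------------------------------

def resize_ratio_preserved(pixels: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Bicubic resize at one isotropic scale, zero-padded to the target frame.

    The scale factor is ``min(target_h/h, target_w/w)`` so the content aspect
    ratio is preserved; the image is anchored at the top-left and the
    remaining rows/columns are zero. Bit depth (dtype) is preserved.
    """
    if target_h <= 0 or target_w <= 0:
        raise ValueError("target dimensions must be positive")
    h, w = pixels.shape
    scale = min(target_h / h, target_w / w)
    if scale == 1.0 and (h, w) == (target_h, target_w):
        return pixels.copy()
    new_h = min(int(round(h * scale)), target_h)
    new_w = min(int(round(w * scale)), target_w)
    resized = sktransform.resize(
        pixels.astype(np.float64), (new_h, new_w), order=3,
        anti_aliasing=scale < 1.0, preserve_range=True,
    )
    out = np.zeros((target_h, target_w))
    out[:new_h, :new_w] = resized
    info = np.iinfo(pixels.dtype) if np.issubdtype(pixels.dtype, np.integer) else None
    if info is not None:
        out = np.clip(np.round(out), info.min, info.max)
    return out.astype(pixels.dtype)


def apply_affine(pixels: np.ndarray, rotation_deg: float = 0.0,
                 scale: float = 1.0, shear_deg: float = 0.0,
                 vertical_flip: bool = False) -> np.ndarray:
    """Affine warp about the image center: bilinear, zero padding, dtype kept."""
    h, w = pixels.shape
    if rotation_deg == 0.0 and scale == 1.0 and shear_deg == 0.0 and not vertical_flip:
        return pixels.copy()
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (
        sktransform.AffineTransform(translation=-center)
        + sktransform.AffineTransform(
            scale=scale,
            rotation=np.deg2rad(rotation_deg),
            shear=np.deg2rad(shear_deg),
        )
        + sktransform.AffineTransform(translation=center)
    )
    src = pixels.astype(np.float64)
    if vertical_flip:
        src = src[::-1, :].copy()
    out = sktransform.warp(src, tf.inverse, order=1, cval=0.0, preserve_range=True)
    info = np.iinfo(pixels.dtype) if np.issubdtype(pixels.dtype, np.integer) else None
    if info is not None:
        out = np.clip(np.round(out), info.min, info.max)
    return out.astype(pixels.dtype)


def augment(pixels: np.ndarray, seed_or_rng) -> np.ndarray:
    """Random training augmentation drawn uniformly from the study's ranges.

    Vertical flip (p=0.5), rotation U(-45, 45) deg, scaling U(0.5, 2),
    shearing U(-45, 45) deg; deterministic given the seed.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return apply_affine(
        pixels,
        rotation_deg=rng.uniform(-45.0, 45.0),
        scale=rng.uniform(0.5, 2.0),
        shear_deg=rng.uniform(-45.0, 45.0),
        vertical_flip=bool(rng.random() < 0.5),
    )


def normalize_for_model(pixels: np.ndarray, n_channels: int = 3) -> np.ndarray:
    """Scale to [0, 1], then standardize with the VGG11 per-channel constants.

    ``n_channels=3`` replicates the grayscale plane into three channels
    before per-channel standardization; ``n_channels=1`` applies the first
    channel's constants only. Returns float64 of shape (C, H, W).
    """
    if n_channels not in (1, 3):
        raise ValueError("n_channels must be 1 or 3")
    x = pixels.astype(np.float64) / U16_MAX
    planes = [(x - VGG_MEAN[c]) / VGG_SD[c] for c in range(n_channels)]
    return np.stack(planes, axis=0)


def denormalize_from_model(stack: np.ndarray) -> np.ndarray:
    """Invert :func:`normalize_for_model` back to the [0, 1] plane."""
    c = stack.shape[0]
    planes = [stack[i] * VGG_SD[i] + VGG_MEAN[i] for i in range(c)]
    return np.mean(planes, axis=0)


def unit_to_u16(plane01: np.ndarray) -> np.ndarray:
    """Map a [0, 1] plane back to 16-bit counts."""
    return np.clip(np.round(plane01 * U16_MAX), 0, U16_MAX).astype(np.uint16)


# ---------------------------------------------------------------------------
# on-disk formats: TIFF + sidecar JSON, manifest CSV, YAML config
# ---------------------------------------------------------------------------

def save_cohort(split: DatasetSplit, out_dir: str | Path) -> Path:
    import tifffile

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for part in ("train", "val", "test"):
        for img in split.partition(part):
            rel = f"images/{img.image_id}.tif"
            tifffile.imwrite(out_dir / rel, img.pixels)
            meta = {
                "patient_id": img.patient_id, "label": img.label,
                "realness": img.realness, "view": img.view,
                "laterality": img.laterality,
                "lesion_specs": [dataclasses.asdict(s) for s in img.lesion_specs],
            }
            (out_dir / rel).with_suffix(".json").write_text(json.dumps(meta))
            rows.append({
                "image_path": rel, "patient_id": img.patient_id,
                "label": img.label, "partition": part,
                "view": img.view, "laterality": img.laterality,
            })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(out_dir: str | Path) -> DatasetSplit:
    import tifffile

    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "manifest.csv")
    partitions: dict[str, list[PhantomImage]] = {"train": [], "val": [], "test": []}
    assignment: dict[str, str] = {}
    for row in df.itertuples():
        meta = json.loads((out_dir / row.image_path).with_suffix(".json").read_text())
        img = PhantomImage(
            pixels=tifffile.imread(out_dir / row.image_path),
            label=meta["label"], realness=meta["realness"],
            patient_id=meta["patient_id"], view=meta["view"],
            laterality=meta["laterality"],
            lesion_specs=[LesionSpec(center=tuple(s["center"]), radius=s["radius"],
                                     peak_contrast=s["peak_contrast"],
                                     n_spicules=s["n_spicules"],
                                     spicule_length=s["spicule_length"])
                          for s in meta["lesion_specs"]],
        )
        partitions[row.partition].append(img)
        assignment[row.patient_id] = row.partition
    return DatasetSplit(assignment=assignment, **partitions)


def config_from_yaml(path: str | Path) -> PhantomConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PhantomConfig:
    kwargs = dict(raw)
    if "background_texture" in kwargs:
        kwargs["background_texture"] = BackgroundTexture(**kwargs["background_texture"])
    if "lesion" in kwargs:
        les = dict(kwargs["lesion"])
        for key in ("radius_range", "peak_contrast_range",
                    "spicule_count_range", "spicule_length_range"):
            if key in les:
                les[key] = tuple(les[key])
        kwargs["lesion"] = LesionParams(**les)
    if "split_fractions" in kwargs:
        kwargs["split_fractions"] = tuple(kwargs["split_fractions"])
    return PhantomConfig(**kwargs).validate()
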