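"""Study orchestration: one config, consistent seeds, resumable stages.

``run_study`` executes the full experiment in dependency order —

    generate-data -> train-cad -> train-gan (remove, insert) -> attack
    -> evaluate -> reader-stats

— writing every artifact under one output directory and registering it in a
``RunManifest`` (JSON) keyed by a hash of the configuration. A re-run with
an unchanged config skips completed stages; changing the config (or passing
``force=True``) invalidates them. All randomness derives from
``master_seed``.

The numbered driver scripts under ``analysis/`` are thin wrappers over the
stage functions here, which is also the command-line surface of the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attack as attack_mod
from . import classifier as classifier_mod
from . import gan as gan_mod
from . import phantom as phantom_mod
from . import reader as reader_mod
from .classifier import (
    BackboneSpec,
    CadClassifier,
    ClassifierLossParams,
    OptimizerSpec,
    TrainedClassifier,
    desk_backbone,
    desk_optimizer,
)
from .gan import AdversarialGenerator, GanLossParams, GanSchedule, UNetGenerator, desk_gan_schedule
from .phantom import DatasetSplit, PhantomConfig

logger = logging.getLogger(__name__)

RESOLUTION_PROFILES = {
    "desk": (128, 104),
    "low": (1024, 832),
    "high": (1728, 1408),
    "custom": None,  # any phantom image size (e.g. miniature test runs)
}


@dataclass
class StudyConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    backbone: BackboneSpec = field(default_factory=desk_backbone)
    optimizer: OptimizerSpec = field(default_factory=desk_optimizer)
    classifier_loss: ClassifierLossParams = field(default_factory=ClassifierLossParams)
    gan_schedule: GanSchedule = field(default_factory=desk_gan_schedule)
    gan_loss: GanLossParams = field(default_factory=GanLossParams)
    threshold: float = 0.5
    n_subgroups: int = 4
    resolution_profile: str = "desk"
    master_seed: int = 0

    def validate(self) -> "StudyConfig":
        errors = []
        try:
            self.phantom.validate()
        except ValueError as e:
            errors.append(f"phantom: {e}")
        try:
            self.backbone.validate()
        except ValueError as e:
            errors.append(f"backbone: {e}")
        try:
            self.optimizer.validate()
        except ValueError as e:
            errors.append(f"optimizer: {e}")
        try:
            self.classifier_loss.validate()
        except ValueError as e:
            errors.append(f"classifier_loss: {e}")
        try:
            self.gan_schedule.validate()
        except ValueError as e:
            errors.append(f"gan_schedule: {e}")
        try:
            self.gan_loss.validate()
        except ValueError as e:
            errors.append(f"gan_loss: {e}")
        if not 0.0 < self.threshold < 1.0:
            errors.append("threshold must lie in (0, 1)")
        if self.n_subgroups < 2:
            errors.append("n_subgroups must be >= 2")
        if self.resolution_profile not in RESOLUTION_PROFILES:
            errors.append(f"unknown resolution profile {self.resolution_profile!r}")
        elif RESOLUTION_PROFILES[self.resolution_profile] is not None:
            h, w = RESOLUTION_PROFILES[self.resolution_profile]
            if (self.phantom.image_height, self.phantom.image_width) != (h, w):
                errors.append(
                    f"phantom image size {self.phantom.image_height}x"
                    f"{self.phantom.image_width} does not match the "
                    f"{self.resolution_profile} profile ({h}x{w})")
        if errors:
            raise ValueError("invalid study config:\n  " + "\n  ".join(errors))
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(source) -> StudyConfig:
    """Build and validate a StudyConfig from YAML (path), dict, or instance.

    Missing fields fall back to documented defaults; a missing master_seed is
    filled with 0 and warned about.
    """
    if isinstance(source, StudyConfig):
        return source.validate()
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    if "master_seed" not in raw:
        logger.warning("no master_seed in config; defaulting to 0")
    kwargs = {}
    if "phantom" in raw:
        kwargs["phantom"] = phantom_mod.config_from_dict(raw["phantom"])
    if "optimizer" in raw:
        kwargs["optimizer"] = OptimizerSpec(**raw["optimizer"])
    if "classifier_loss" in raw:
        kwargs["classifier_loss"] = ClassifierLossParams(**raw["classifier_loss"])
    if "gan_loss" in raw:
        kwargs["gan_loss"] = GanLossParams(**raw["gan_loss"])
    if "gan_schedule" in raw:
        gs = dict(raw["gan_schedule"])
        for phase in ("phase_a", "phase_b"):
            if phase in gs:
                gs[phase] = gan_mod.PhaseSpec(**gs[phase])
        kwargs["gan_schedule"] = GanSchedule(**gs)
    for key in ("threshold", "n_subgroups", "resolution_profile", "master_seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return StudyConfig(**kwargs).validate()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path, manifest: dict):
    path = Path(path)
    np.savez(path, **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(manifest, default=str, indent=1))


def load_classifier(path: str | Path, spec: BackboneSpec | None = None) -> CadClassifier:
    state = dict(np.load(Path(path)))
    model = CadClassifier(spec or desk_backbone())
    model.load_state_dict(state)
    model.eval()
    return model


def load_generator(path: str | Path) -> UNetGenerator:
    state = dict(np.load(Path(path)))
    model = UNetGenerator()
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# the run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    stages: dict[str, bool] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    def save(self, out_dir: Path):
        (out_dir / "run_manifest.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, out_dir: Path) -> "RunManifest | None":
        f = out_dir / "run_manifest.json"
        if not f.exists():
            return None
        return cls(**json.loads(f.read_text()))

    def stage_done(self, name: str, out_dir: Path) -> bool:
        if not self.stages.get(name, False):
            return False
        return all((out_dir / p).exists()
                   for k, p in self.artifacts.items() if k.startswith(name))


def _stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig, out_dir: str | Path,
              force: bool = False) -> RunManifest:
    """Execute all stages; resumable. Returns the populated manifest."""
    config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    previous = RunManifest.load(out_dir)
    if previous is None or previous.config_hash != chash or force:
        manifest = RunManifest(
            config_hash=chash,
            seeds={s: _stage_seed(config.master_seed, s)
                   for s in ("data", "cad", "gan_remove", "gan_insert", "reader")},
            versions={"python": platform.python_version(),
                      "numpy": np.__version__},
        )
    else:
        manifest = previous
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=1, default=str))

    # ---- generate-data ----------------------------------------------------
    cohort_dir = out_dir / "cohort"
    if force or not manifest.stage_done("data", out_dir):
        cfg = dataclasses.replace(config.phantom, seed=manifest.seeds["data"])
        split = phantom_mod.generate_cohort(cfg)
        phantom_mod.save_cohort(split, cohort_dir)
        manifest.stages["data"] = True
        manifest.artifacts["data.manifest"] = "cohort/manifest.csv"
        manifest.save(out_dir)
        logger.info("stage data: %d/%d/%d train/val/test images",
                    len(split.train), len(split.val), len(split.test))
    else:
        split = phantom_mod.load_cohort(cohort_dir)
        logger.info("stage data: reused existing cohort")

    # ---- train-cad --------------------------------------------------------
    cad_path = out_dir / "classifier.npz"
    if force or not manifest.stage_done("cad", out_dir):
        trained = classifier_mod.train_classifier(
            split, spec=config.backbone, opt=config.optimizer,
            loss_params=config.classifier_loss, seed=manifest.seeds["cad"])
        save_model(trained.model, cad_path, {
            "kind": "cad_classifier", "mode": config.backbone.mode,
            "best_epoch": trained.best_epoch,
            "best_val_auc": trained.best_val_auc,
        })
        trained.log.to_csv(out_dir / "classifier_log.csv", index=False)
        manifest.stages["cad"] = True
        manifest.artifacts["cad.checkpoint"] = "classifier.npz"
        manifest.artifacts["cad.log"] = "classifier_log.csv"
        manifest.save(out_dir)
        cad = trained
        logger.info("stage cad: best val AUC %.3f", trained.best_val_auc)
    else:
        model = load_classifier(cad_path, config.backbone)
        log = pd.read_csv(out_dir / "classifier_log.csv")
        meta = json.loads(cad_path.with_suffix(".json").read_text())
        cad = TrainedClassifier(model=model, spec=config.backbone, log=log,
                                best_epoch=meta["best_epoch"],
                                best_val_auc=meta["best_val_auc"])
        logger.info("stage cad: reused checkpoint (val AUC %.3f)", cad.best_val_auc)

    # ---- train-gan (both directions) --------------------------------------
    generators: dict[str, AdversarialGenerator] = {}
    for direction, stage in (("remove_lesion", "gan_remove"),
                             ("insert_lesion", "gan_insert")):
        gpath = out_dir / f"generator_{direction}.npz"
        if force or not manifest.stage_done(stage, out_dir):
            g = gan_mod.train_gan(direction, split, cad,
                                  schedule=config.gan_schedule,
                                  loss_params=config.gan_loss,
                                  seed=manifest.seeds[stage])
            save_model(g.model, gpath, {"kind": "unet_generator",
                                        "direction": direction})
            g.log.to_csv(out_dir / f"gan_log_{direction}.csv", index=False)
            manifest.stages[stage] = True
            manifest.artifacts[f"{stage}.checkpoint"] = gpath.name
            manifest.artifacts[f"{stage}.log"] = f"gan_log_{direction}.csv"
            manifest.save(out_dir)
            generators[direction] = g
        else:
            generators[direction] = AdversarialGenerator(
                model=load_generator(gpath), direction=direction,
                schedule=config.gan_schedule,
                log=pd.read_csv(out_dir / f"gan_log_{direction}.csv"),
                update_log=[])
            logger.info("stage %s: reused checkpoint", stage)

    # ---- attack + evaluate -------------------------------------------------
    records = []
    pair_rows = []
    fake_dir = out_dir / "fakes"
    fake_dir.mkdir(exist_ok=True)
    import tifffile
    for img in split.test:
        direction = ("remove_lesion" if img.label == "positive"
                     else "insert_lesion")
        pair = gan_mod.generate_adversarial(generators[direction], img)
        prob_real = classifier_mod.predict_prob(cad.model, pair.real)
        prob_fake = classifier_mod.predict_prob(cad.model, pair.fake)
        records.append(attack_mod.AttackRecord(
            image_id=img.image_id, true_label=img.label,
            prob_real=prob_real, prob_fake=prob_fake))
        fake_path = f"fakes/{img.image_id}_fake.tif"
        tifffile.imwrite(out_dir / fake_path, pair.fake.pixels)
        pair_rows.append({"image_id": img.image_id, "true_label": img.label,
                          "direction": direction, "fake_path": fake_path,
                          "prob_real": prob_real, "prob_fake": prob_fake})
    pd.DataFrame(pair_rows).to_csv(out_dir / "attack_pairs.csv", index=False)
    report = attack_mod.fool_rate_report(records, threshold=config.threshold)
    (out_dir / "fool_rate_report.json").write_text(
        json.dumps(report.to_dict(), indent=1))
    (out_dir / "fool_rate_report.txt").write_text(report.to_text() + "\n")
    manifest.stages["attack"] = True
    manifest.artifacts["attack.pairs"] = "attack_pairs.csv"
    manifest.artifacts["attack.report"] = "fool_rate_report.json"

    # education panels for the first few positive pairs
    shown = 0
    for row in pair_rows:
        if row["direction"] != "remove_lesion" or shown >= 3:
            continue
        real_img = next(i for i in split.test if i.image_id == row["image_id"])
        fake_px = tifffile.imread(out_dir / row["fake_path"])
        attack_mod.save_education_panel(
            real_img.pixels, fake_px,
            out_dir / f"education_panel_{shown}.png",
            out_diff_tif=out_dir / f"education_panel_{shown}_difference.tif")
        shown += 1

    # ---- reader statistics -------------------------------------------------
    responses = reader_mod.simulate_reader_responses(seed=manifest.seeds["reader"])
    responses.to_csv(out_dir / "reader_responses.csv", index=False)
    table = reader_mod.reader_table(responses)
    table.to_csv(out_dir / "reader_table.csv", index=False)
    table.to_json(out_dir / "reader_table.json", orient="records", indent=1)
    comparisons = reader_mod.compare_all_sessions(
        responses, n_subgroups=config.n_subgroups)
    comparisons.to_csv(out_dir / "reader_comparisons.csv", index=False)
    manifest.stages["reader"] = True
    manifest.artifacts["reader.table"] = "reader_table.csv"
    manifest.artifacts["reader.comparisons"] = "reader_comparisons.csv"
    manifest.save(out_dir)
    logger.info("study complete: pooled fool rate %s%%",
                report.pct_fooled_pooled)
    return manifest
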