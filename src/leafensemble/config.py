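"""Run configuration: YAML loading, defaulting, validation, profiles.

A run config nests the per-stage configs (dataset, augmentation,
segmenters, classifiers, fusion, ensemble) plus an output directory,
a master seed and a profile tag.  The ``desk`` profile is the tested,
CPU-minutes-scale setup; the ``paper`` profile carries the full-scale
training configuration (lr 0.001, batch 32, Adam, 200 epochs, 224 px,
38 classes) and is provided for fidelity, not exercised by the tests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classification import CoAtNetConfig, EnhancedCoAtNetConfig
from .fusion import LFHBAConfig
from .preprocess import AugmentationPlan
from .segmentation import SegEnsembleConfig, SwinSegConfig, TrainConfig, UNetConfig
from .synthetic import DatasetSpec, ValidationError

logger = logging.getLogger(__name__)

DESK_CAPS = {"epochs": 20, "image_size": 64, "n_classes": 10}


@dataclass
class RunConfig:
    dataset: DatasetSpec
    augment: AugmentationPlan
    unet: UNetConfig
    swin: SwinSegConfig
    coatnet: CoAtNetConfig
    enhanced: EnhancedCoAtNetConfig
    seg_train: TrainConfig
    swin_train: TrainConfig
    clf_train: TrainConfig
    enhanced_train: TrainConfig
    lfhba: LFHBAConfig
    ensemble: SegEnsembleConfig
    output_dir: str = "runs/out"
    seed: int = 0
    profile: str = "desk"
    use_augmentation: bool = False

    def __post_init__(self):
        if self.profile not in ("desk", "paper"):
            raise ValidationError(f"profile must be desk or paper, got '{self.profile}'")
        if self.profile == "desk":
            caps = DESK_CAPS
            if self.seg_train.epochs > caps["epochs"] or \
               self.clf_train.epochs > caps["epochs"]:
                raise ValidationError(
                    f"desk profile caps epochs at {caps['epochs']}")
            if self.dataset.image_size > caps["image_size"]:
                raise ValidationError(
                    f"desk profile caps image_size at {caps['image_size']}")
            if self.dataset.n_classes > caps["n_classes"]:
                raise ValidationError(
                    f"desk profile caps n_classes at {caps['n_classes']}")


def desk_config(n_classes: int = 5, images_per_class: int = 100,
                image_size: int = 64, seed: int = 0,
                output_dir: str = "runs/desk") -> RunConfig:
    """The tested desk-scale configuration: tiny networks, minutes on one
    CPU core, separable synthetic classes."""
    return RunConfig(
        dataset=DatasetSpec(n_classes=n_classes, images_per_class=images_per_class,
                            image_size=image_size, seed=seed),
        augment=AugmentationPlan(seed=seed),
        unet=UNetConfig(depth=3, base_channels=8),
        swin=SwinSegConfig(input_size=image_size, embed_dim=24, depths=(2, 2),
                           n_heads=(2, 4), window_size=4),
        coatnet=CoAtNetConfig(stage_layout=("conv", "conv", "transformer"),
                              channels=(8, 16, 32), blocks_per_stage=(1, 1, 1),
                              n_heads=4, n_classes=n_classes, input_size=image_size),
        enhanced=EnhancedCoAtNetConfig(
            base=CoAtNetConfig(stage_layout=("conv", "conv", "transformer"),
                               channels=(8, 16, 32), blocks_per_stage=(1, 1, 1),
                               n_heads=4, n_classes=n_classes,
                               input_size=image_size),
            n_scales=3),
        seg_train=TrainConfig(learning_rate=0.003, batch_size=16, epochs=12,
                              seed=seed),
        swin_train=TrainConfig(learning_rate=0.005, batch_size=16, epochs=12,
                               seed=seed),
        clf_train=TrainConfig(learning_rate=0.002, batch_size=32, epochs=12,
                              seed=seed),
        enhanced_train=TrainConfig(learning_rate=0.002, batch_size=32, epochs=12,
                                   seed=seed),
        lfhba=LFHBAConfig(population_size=20, iterations=60, seed=seed),
        ensemble=SegEnsembleConfig(),
        output_dir=output_dir,
        seed=seed,
        profile="desk",
    )


def paper_config(seed: int = 0, output_dir: str = "runs/paper") -> RunConfig:
    """Full-scale profile: 38 classes at 224 px, Adam at lr 0.001, batch
    32, 200 epochs.  Provided for completeness; not exercised by tests."""
    train = TrainConfig(learning_rate=0.001, batch_size=32, epochs=200, seed=seed)
    return RunConfig(
        dataset=DatasetSpec(n_classes=38, images_per_class=100, image_size=224,
                            seed=seed),
        augment=AugmentationPlan(seed=seed),
        unet=UNetConfig(depth=4, base_channels=16),
        swin=SwinSegConfig(input_size=224, patch_size=4, embed_dim=32,
                           depths=(2, 2), n_heads=(2, 4), window_size=7),
        coatnet=CoAtNetConfig(n_classes=38, input_size=224,
                              channels=(16, 32, 64, 64)),
        enhanced=EnhancedCoAtNetConfig(
            base=CoAtNetConfig(n_classes=38, input_size=224,
                               channels=(16, 32, 64, 64))),
        seg_train=train,
        swin_train=train,
        clf_train=train,
        enhanced_train=train,
        lfhba=LFHBAConfig(seed=seed),
        ensemble=SegEnsembleConfig(),
        output_dir=output_dir,
        seed=seed,
        profile="paper",
    )


# --------------------------------------------------------------------------
# YAML loading

_SECTION_BUILDERS = {
    "dataset": DatasetSpec,
    "augment": AugmentationPlan,
    "unet": UNetConfig,
    "swin": SwinSegConfig,
    "coatnet": CoAtNetConfig,
    "enhanced": EnhancedCoAtNetConfig,
    "seg_train": TrainConfig,
    "swin_train": TrainConfig,
    "clf_train": TrainConfig,
    "enhanced_train": TrainConfig,
    "lfhba": LFHBAConfig,
    "ensemble": SegEnsembleConfig,
}

_TUPLE_FIELDS = {"depths", "n_heads", "stage_layout", "channels", "blocks_per_stage",
                 "operations", "lesion_count_range", "lesion_radius_range",
                 "lesion_color", "lighting_jitter", "bounds", "target_accuracies",
                 "member_weights", "rotation_degrees", "scale_range",
                 "brightness_range", "contrast_range", "lambda_init", "alpha_init"}


def _build_section(base_obj, data: dict, errors: list[str], path: str):
    """Overlay YAML keys onto the profile's section defaults."""
    cls = type(base_obj)
    known = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            logger.warning("unknown config key %s.%s ignored", path, key)
            continue
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        if key == "base" and isinstance(value, dict):
            value = _build_section(base_obj.base, value, errors, f"{path}.base")
            if value is None:
                continue
        kwargs[key] = value
    if cls is DatasetSpec and "n_classes" in kwargs and "class_styles" not in kwargs:
        kwargs["class_styles"] = None    # regenerate styles for the new class count
    try:
        return dataclasses.replace(base_obj, **kwargs)
    except (ValidationError, TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return None


def validate_config(path) -> RunConfig:
    """Parse a YAML run config into a fully defaulted :class:`RunConfig`.

    Unknown keys warn (forward compatibility); invalid values raise a
    single :class:`ValidationError` listing every violation with its key
    path.
    """
    p = Path(path)
    raw = yaml.safe_load(p.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    profile = raw.get("profile", "desk")
    seed = int(raw.get("seed", 0))
    base = desk_config(seed=seed) if profile == "desk" else paper_config(seed=seed)
    errors: list[str] = []
    updates = {}
    for key, value in raw.items():
        if key in ("profile", "seed"):
            continue
        if key == "output_dir":
            updates["output_dir"] = str(value)
            continue
        if key == "use_augmentation":
            updates["use_augmentation"] = bool(value)
            continue
        if key not in _SECTION_BUILDERS:
            logger.warning("unknown config section '%s' ignored", key)
            continue
        if not isinstance(value, dict):
            errors.append(f"{key}: expected a mapping")
            continue
        built = _build_section(getattr(base, key), value, errors, key)
        if built is not None:
            updates[key] = built
    if errors:
        raise ValidationError("invalid config:\n  " + "\n  ".join(errors))
    cfg = dataclasses.replace(base, profile=profile, seed=seed, **updates)
    return cfg


def config_fingerprint(obj) -> str:
    """Stable hash of a (nested) dataclass configuration."""
    import hashlib
    import json

    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, dict):
            return {k: enc(v) for k, v in sorted(o.items())}
        if hasattr(o, "tolist"):
            return o.tolist()
        return o

    blob = json.dumps(enc(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
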