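"""End-to-end orchestration: simulate -> reconstruct -> segment -> augment
-> train -> ensemble, as a single reproducible run.

Two entry points mirror the two experimental phases of a test-slide study:

* :func:`run_dry_slide_training` — image a phantom "dry slide" in focus,
  reconstruct and segment one generator WQPI per class, expand each through
  the augmentation lattice, and train a max-voting ensemble.
* :func:`run_wet_test` — render independent "wet" fixtures (the same
  species re-drawn at random orientation/size/bias, recorded out of focus
  in a noisy single-object hologram), refocus each by Tamura autofocus, and
  evaluate the trained ensemble on them.

One global seed fans out to per-stage seeds by fixed offsets; all reported
numbers are deterministic for a fixed config.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .augment import (
    AugmentationGrid,
    _trim_support,
    apply_transform,
    build_grid,
    generate_dataset,
    split_train_val,
)
from .classify import (
    ConfusionMatrix,
    ImageDataset,
    TrainConfig,
    TrainedModel,
    ensemble_predict,
    evaluate,
    train_model,
)
from .config import OpticalConfig, carrier_on_grid
from .phase import WQPI, wrap_phase
from .reconstruct import (
    autofocus,
    compensate_piston,
    demodulate,
    extract_wqpi,
    propagate,
)
from .segment import match_to_truth, segment_slide
from .simulate import MorphologyConfig, PhantomSlide, form_hologram, make_phantom_slide

__all__ = ["GridSpec", "WetConfig", "RunConfig", "DryRunArtifacts",
           "run_dry_slide_training", "run_wet_test"]

logger = logging.getLogger("holoplankton.pipeline")

# Fixed per-stage seed offsets fanned out from the global seed.
_SEED_SLIDE = 11
_SEED_HOLOGRAM = 13
_SEED_PLAN = 17
_SEED_SPLIT = 19
_SEED_TRAIN = 23
_SEED_WET = 29


@dataclass(frozen=True)
class GridSpec:
    """Serializable parameters of the augmentation lattice."""

    scale_extent: float = 0.20
    n_scales: int = 21
    angle_step_deg: float = 10.0
    n_biases: int = 11

    def build(self) -> AugmentationGrid:
        return build_grid(
            scale_extent=self.scale_extent,
            n_scales=self.n_scales,
            angle_step_deg=self.angle_step_deg,
            n_biases=self.n_biases,
        )


@dataclass(frozen=True)
class WetConfig:
    """Wet-fixture rendering and evaluation parameters.

    Each test object is re-rendered from the ground-truth phantom of its
    class with a random rotation, per-axis size change and phase bias
    (drawn from the same ranges the training lattice spans), embedded in a
    small single-object hologram recorded out of focus (uniform defocus in
    ``[-defocus_max, defocus_max]`` meters) with additive intensity noise,
    and refocused by Tamura autofocus over ``[-z_search, z_search]``.
    """

    n_per_class: int = 20
    defocus_max: float = 3.5e-3
    noise_sd: float = 0.05
    z_search: float = 4.0e-3
    canvas_px: int = 128
    classes: tuple[int, ...] | None = None  # None = all trained classes


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a reproducible end-to-end run."""

    seed: int = 0
    n_classes: int = 5
    slide_shape: tuple[int, int] = (512, 512)
    wavelength: float = 532e-9
    pixel_pitch: float = 5.5e-6
    carrier_cycles_frac: float = 0.35  # carrier cycles per axis = frac * N
    filter_radius_frac: float = 0.5  # bandpass radius as fraction of carrier
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    # Same camera read noise in the dry (training) recording as in the wet
    # recordings: both phases share one instrument.
    dry_noise_sd: float = 0.05
    min_area_px: int = 100
    pad_px: int = 8
    grid: GridSpec = field(default_factory=GridSpec)
    per_class: int = 500
    train_frac: float = 0.8
    canvas_px: int = 56  # augmented-image canvas
    # From-scratch desk-scale training: lr 0.01 (the 0.001 protocol default
    # targets fine-tuning of pretrained networks and converges too slowly
    # for a small CNN trained from random init).
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            learning_rate=0.01, crop_px=56, downsample=2, max_epochs=50
        )
    )
    ensemble: tuple[str, ...] = ("tiny_cnn", "tiny_cnn_narrow", "tiny_cnn_wide")
    wet: WetConfig = field(default_factory=WetConfig)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "morphology" in d and isinstance(d["morphology"], dict):
            m = dict(d["morphology"])
            for key in ("radius_range", "aspect_range", "peak_phase_range",
                        "ridge_period_range", "families"):
                if key in m:
                    m[key] = tuple(m[key])
            d["morphology"] = MorphologyConfig(**m)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = GridSpec(**d["grid"])
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "wet" in d and isinstance(d["wet"], dict):
            w = dict(d["wet"])
            if w.get("classes") is not None:
                w["classes"] = tuple(w["classes"])
            d["wet"] = WetConfig(**w)
        for key in ("slide_shape", "ensemble"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    # -- derived optics ------------------------------------------------
    def optics_for(self, shape: tuple[int, int]) -> OpticalConfig:
        ny, nx = shape
        fx, fy = carrier_on_grid(
            shape,
            self.pixel_pitch,
            cycles_y=int(round(self.carrier_cycles_frac * ny)),
            cycles_x=int(round(self.carrier_cycles_frac * nx)),
        )
        return OpticalConfig(
            wavelength=self.wavelength,
            pixel_pitch=self.pixel_pitch,
            carrier_fx=fx,
            carrier_fy=fy,
            sensor_ny=ny,
            sensor_nx=nx,
        )


@dataclass
class DryRunArtifacts:
    """Objects produced by the dry-slide training run, kept for the wet test."""

    slide: PhantomSlide
    generators: list[WQPI]
    models: list[TrainedModel]
    class_ids: tuple[int, ...]
    report: dict


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_dry_slide_training(config: RunConfig) -> DryRunArtifacts:
    """Execute the full dry-slide chain and train the ensemble.

    Returns the artifacts (slide, per-class generator WQPIs, trained
    models) together with a JSON-serializable ``report`` recording object
    counts per stage, the grid cardinality, split sizes and per-model
    validation accuracies.  Fails loudly (:class:`StageError`) on any stage
    inconsistency, e.g. a segmentation count different from ``n_classes``.
    """
    seed = config.seed
    optics = config.optics_for(config.slide_shape)
    report: dict = {"seed": seed, "n_classes": config.n_classes}

    @_stage("simulate")
    def _simulate():
        slide = make_phantom_slide(
            config.n_classes, config.slide_shape, config.morphology,
            seed=seed + _SEED_SLIDE,
        )
        holo = form_hologram(slide, optics, defocus_z=0.0,
                             noise_sd=config.dry_noise_sd,
                             seed=seed + _SEED_HOLOGRAM)
        return slide, holo

    slide, holo = _simulate()
    logger.info("simulate: %d objects on %s", len(slide.objects), config.slide_shape)

    @_stage("reconstruct")
    def _reconstruct():
        fld = demodulate(
            holo, filter_radius=config.filter_radius_frac * optics.carrier_magnitude
        )
        return extract_wqpi(compensate_piston(fld))

    full_wqpi = _reconstruct()

    @_stage("segment")
    def _segment():
        objs = segment_slide(full_wqpi, config.min_area_px, config.pad_px)
        if len(objs) != config.n_classes:
            raise ValueError(
                f"segmented {len(objs)} objects, expected {config.n_classes}"
            )
        truth = {o.class_id: o.centroid for o in slide.objects}
        match_to_truth(objs, truth)
        return objs

    objs = _segment()
    generators = [o.wqpi_crop for o in sorted(objs, key=lambda o: o.class_id)]
    report["segmented_objects"] = len(objs)
    logger.info("segment: %d generator WQPIs", len(objs))

    @_stage("augment")
    def _augment():
        grid = config.grid.build()
        manifest, images = generate_dataset(
            generators, grid, config.per_class, seed=seed + _SEED_PLAN,
            out_shape=(config.canvas_px, config.canvas_px),
        )
        train_m, val_m = split_train_val(
            manifest, config.train_frac, seed=seed + _SEED_SPLIT
        )
        return grid, manifest, images, train_m, val_m

    grid, manifest, images, train_m, val_m = _augment()
    class_ids = tuple(g.class_id for g in generators)
    report["grid_cardinality"] = grid.cardinality
    report["per_class"] = config.per_class
    report["dataset_size"] = len(manifest)
    report["split"] = {
        "train": len(train_m),
        "val": len(val_m),
        "train_per_class": int(len(train_m) // len(class_ids)),
        "val_per_class": int(len(val_m) // len(class_ids)),
    }
    logger.info("augment: %d images, split %d/%d", len(manifest), len(train_m), len(val_m))

    @_stage("train")
    def _train():
        train_ds = ImageDataset.from_manifest(train_m, images, class_ids)
        val_ds = ImageDataset.from_manifest(val_m, images, class_ids)
        models = []
        for i, arch in enumerate(config.ensemble):
            tc = replace(config.train, seed=seed + _SEED_TRAIN + i)
            model = train_model(train_ds, val_ds, arch, tc)
            val_res = evaluate(model, val_ds)
            models.append((model, val_res))
            logger.info(
                "train: %s val_acc=%.3f best_epoch=%d",
                arch, val_res.accuracy, model.log.best_epoch,
            )
        return models

    trained = _train()
    report["models"] = [
        {
            "name": m.name,
            "val_accuracy": res.accuracy,
            "best_epoch": m.log.best_epoch,
            "stopped_epoch": m.log.stopped_epoch,
            "n_parameters": m.net.n_parameters,
        }
        for m, res in trained
    ]
    return DryRunArtifacts(
        slide=slide,
        generators=generators,
        models=[m for m, _ in trained],
        class_ids=class_ids,
        report=report,
    )


def _fit_canvas(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Center an image on a phase-0 canvas, center-cropping if oversized."""
    ny, nx = out_shape
    if img.shape[0] > ny:
        r0 = (img.shape[0] - ny) // 2
        img = img[r0 : r0 + ny, :]
    if img.shape[1] > nx:
        c0 = (img.shape[1] - nx) // 2
        img = img[:, c0 : c0 + nx]
    canvas = np.zeros(out_shape)
    r0 = (ny - img.shape[0]) // 2
    c0 = (nx - img.shape[1]) // 2
    canvas[r0 : r0 + img.shape[0], c0 : c0 + img.shape[1]] = img
    return canvas


def _render_wet_object(
    config: RunConfig,
    slide: PhantomSlide,
    class_id: int,
    rng: np.random.Generator,
):
    """One wet fixture: transformed ground-truth phase in a small volume."""
    patch = slide.object_patch(class_id, pad_px=2)
    # Wrapping the ground truth changes nothing physically (exp(i psi) is
    # 2*pi-periodic) and keeps the WQPI contract for the pose transform.
    wq = WQPI(wrap_phase(patch), pixel_pitch=config.pixel_pitch)
    ext = config.grid.scale_extent
    posed = apply_transform(
        wq,
        scale_x=rng.uniform(-ext, ext),
        scale_y=rng.uniform(-ext, ext),
        angle_deg=rng.uniform(0.0, 360.0),
        bias_rad=0.0,
        out_shape=(config.wet.canvas_px, config.wet.canvas_px),
    )
    defocus = rng.uniform(-config.wet.defocus_max, config.wet.defocus_max)
    return posed.phase, defocus


def run_wet_test(config: RunConfig, artifacts: DryRunArtifacts) -> dict:
    """Simulate wet fixtures, refocus, classify with the ensemble.

    Returns a report with the ensemble accuracy, the full confusion matrix,
    the matrix restricted to the test classes, and the per-object autofocus
    results.
    """
    wet = config.wet
    classes = wet.classes or artifacts.class_ids
    unknown = set(classes) - set(artifacts.class_ids)
    if unknown:
        raise ValueError(f"wet test classes {sorted(unknown)} were not trained")
    wet_shape = (wet.canvas_px, wet.canvas_px)
    optics = config.optics_for(wet_shape)
    half = config.canvas_px  # classifier canvas

    images, labels, focus_rows = [], [], []
    streams = np.random.SeedSequence(config.seed + _SEED_WET).spawn(
        len(classes) * wet.n_per_class
    )

    @_stage("wet_fixtures")
    def _fixtures():
        i = 0
        for cid in classes:
            for _ in range(wet.n_per_class):
                rng = np.random.default_rng(streams[i])
                i += 1
                phase, defocus = _render_wet_object(config, artifacts.slide, cid, rng)
                wet_slide = PhantomSlide(
                    true_phase=phase,
                    label_map=(phase != 0).astype(int) * cid,
                    objects=[],
                    rng_seed=config.seed,
                )
                holo = form_hologram(
                    wet_slide, optics, defocus_z=defocus,
                    noise_sd=wet.noise_sd, seed=int(rng.integers(2**31)),
                )
                fld = demodulate(
                    holo,
                    filter_radius=config.filter_radius_frac * optics.carrier_magnitude,
                )
                scan = autofocus(fld, -wet.z_search, wet.z_search)
                focused = compensate_piston(propagate(fld, scan.z_best))
                wqpi = extract_wqpi(focused)
                segs = segment_slide(wqpi, config.min_area_px, config.pad_px)
                if segs:
                    crop = max(segs, key=lambda o: o.area_px).wqpi_crop.phase
                else:  # pathological fixture (e.g. failed refocus): whole field
                    crop = wqpi.phase
                # Trim to the object support (the geometry the augmented
                # training images have), then apply a random residual phase
                # offset — the effect the bias augmentation exists to cover.
                crop = _trim_support(crop)
                crop = wrap_phase(crop + rng.uniform(0.0, np.pi))
                img = _fit_canvas(crop, (half, half))
                images.append(img)
                labels.append(cid)
                focus_rows.append(
                    {
                        "class_id": int(cid),
                        "true_refocus_z": float(-defocus),
                        "z_best": float(scan.z_best),
                        "in_range": bool(abs(scan.z_best) < wet.z_search),
                    }
                )

    _fixtures()

    @_stage("evaluate")
    def _evaluate():
        test_ds = ImageDataset(
            np.stack(images), np.array(labels), artifacts.class_ids
        )
        preds = ensemble_predict(artifacts.models, test_ds)
        acc = float((preds.voted_labels == test_ds.labels).mean())
        cm = ConfusionMatrix.from_predictions(
            test_ds.labels, preds.voted_labels, artifacts.class_ids
        )
        per_model = [
            float((preds.per_model_labels[i] == test_ds.labels).mean())
            for i in range(len(artifacts.models))
        ]
        return acc, cm, per_model

    acc, cm, per_model = _evaluate()
    restricted = cm.restrict(classes)
    report = {
        "seed": config.seed,
        "test_classes": [int(c) for c in classes],
        "n_test_objects": len(labels),
        "ensemble_accuracy": acc,
        "per_model_accuracy": per_model,
        "confusion_full": cm.counts.tolist(),
        "confusion_restricted": restricted.counts.tolist(),
        "confusion_restricted_classes": [int(c) for c in restricted.class_ids],
        "autofocus": focus_rows,
    }
    logger.info("wet test: ensemble accuracy %.3f on %d objects", acc, len(labels))
    return report
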