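"""Random-forest pixel classifiers and the hierarchical three-step pipeline.

Stages 2 and 3 of the pipeline are trainable pixel classifiers in the
QuPath/ilastik tradition: a random forest fitted on multiscale features at
sparsely brush-annotated pixels only, then applied densely inside the mask
produced by the previous stage. Stage 2 separates mucosa from
submucosa/muscularis inside the detected tissue at 7.03 µm/px; stage 3
separates epithelium from lamina propria inside the mucosa at 3.51 µm/px.
Forest defaults (100 trees, sqrt feature subsetting, unlimited depth, no
class weighting) are recorded in the training manifest together with the
seed and exact annotation counts, so a trained model is reproducible from
its manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import (
    STEP2_FEATURES,
    STEP3_FEATURES,
    FeatureConfig,
    compute_feature_stack,
    resample,
)
from .image import UNCLASSIFIED, AnnotationSet, CalibratedImage, LabelMask
from .stain import estimate_stain_vectors, hematoxylin_channel
from .tissue import (
    STEP1_MIN_HOLE_UM2,
    STEP1_MIN_OBJECT_UM2,
    STEP3_MIN_HOLE_UM2,
    STEP3_MIN_OBJECT_UM2,
    RegionObjects,
    ThresholdConfig,
    create_objects,
    threshold_tissue,
)

DEFAULT_RF_PARAMS = {
    "n_estimators": 100,
    "max_features": "sqrt",
    "max_depth": None,
    "n_jobs": 1,
}


def prepare_channels(
    image: CalibratedImage, config: FeatureConfig
) -> tuple[CalibratedImage, dict[str, np.ndarray]]:
    """Resample to the working resolution and build the channel dict.

    The hematoxylin channel is deconvolved with stain vectors refit on this
    image (per-image colour normalisation); R, G, B are the raw colour
    channels as floats.
    """
    if image.pixel_size_um < config.working_resolution_um - 1e-9:
        image = resample(image, config.working_resolution_um)
    px = image.pixels.astype(np.float64)
    channels: dict[str, np.ndarray] = {}
    for name in config.channels:
        if name == "R":
            channels[name] = px[:, :, 0]
        elif name == "G":
            channels[name] = px[:, :, 1]
        elif name == "B":
            channels[name] = px[:, :, 2]
        elif name == "hematoxylin":
            model = estimate_stain_vectors(image)
            channels[name] = hematoxylin_channel(image, model)
    return image, channels


@dataclass
class TrainedPixelClassifier:
    """A fitted forest bundled with everything needed to re-apply it."""

    forest: RandomForestClassifier
    feature_config: FeatureConfig
    classes: tuple[str, ...]
    manifest: dict = field(default_factory=dict)
    version: str = "1"

    def check_compatible(self, config: FeatureConfig) -> None:
        if config != self.feature_config:
            raise ValueError(
                "feature configuration mismatch: model was trained with "
                f"{self.feature_config}, got {config}"
            )

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "forest": self.forest,
                "feature_config_yaml": self.feature_config.to_yaml(),
                "classes": list(self.classes),
                "manifest": self.manifest,
                "version": self.version,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPixelClassifier":
        d = joblib.load(path)
        return cls(
            forest=d["forest"],
            feature_config=FeatureConfig.from_yaml(d["feature_config_yaml"]),
            classes=tuple(d["classes"]),
            manifest=d["manifest"],
            version=d["version"],
        )


def train_classifier(
    samples: list[tuple[CalibratedImage, AnnotationSet]],
    cfg: FeatureConfig,
    classes: tuple[str, ...],
    rf_params: dict | None = None,
    seed: int = 0,
) -> TrainedPixelClassifier:
    """Fit a random-forest pixel classifier on brush-annotated pixels.

    Training rows are the features at annotated pixel locations only — no
    background sampling. Every declared class must be annotated at least
    once across the sample set, and at least two classes must be present.
    Deterministic for a fixed seed.
    """
    if len(classes) < 2:
        raise ValueError("at least two classes are required")
    params = {**DEFAULT_RF_PARAMS, **(rf_params or {})}

    rows: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    counts: dict[str, int] = {c: 0 for c in classes}
    sample_counts = []
    for i, (image, annotations) in enumerate(samples):
        image, channels = prepare_channels(image, cfg)
        stack = compute_feature_stack(channels, cfg)
        per_sample = {}
        for ci, class_name in enumerate(classes):
            rr, cc = annotations.pixel_indices(class_name)
            if rr.size == 0:
                per_sample[class_name] = 0
                continue
            rows.append(stack.at(rr, cc))
            labels.append(np.full(rr.size, ci, dtype=np.int64))
            counts[class_name] += int(rr.size)
            per_sample[class_name] = int(rr.size)
        sample_counts.append(per_sample)
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise ValueError(f"no annotated pixels for class(es): {missing}")

    x = np.concatenate(rows)
    y = np.concatenate(labels)
    forest = RandomForestClassifier(random_state=seed, **params)
    forest.fit(x, y)
    manifest = {
        "n_samples": len(samples),
        "annotated_pixels_per_class": counts,
        "per_sample_pixels": sample_counts,
        "n_training_rows": int(y.size),
        "rf_params": params,
        "seed": seed,
        "classes": list(classes),
    }
    return TrainedPixelClassifier(
        forest=forest, feature_config=cfg, classes=tuple(classes), manifest=manifest
    )


def apply_classifier(
    model: TrainedPixelClassifier,
    image: CalibratedImage,
    restrict_mask: np.ndarray | None = None,
    feature_config: FeatureConfig | None = None,
) -> LabelMask:
    """Classify every pixel inside the restriction mask.

    Pixels outside ``restrict_mask`` stay unclassified (-1) and never carry
    a class. Inside, the label is the argmax of forest votes, ties broken
    toward the first class in the declared class order. Passing a
    ``feature_config`` different from the training one is refused.
    """
    if feature_config is not None:
        model.check_compatible(feature_config)
    image, channels = prepare_channels(image, model.feature_config)
    h, w = image.shape
    if restrict_mask is None:
        restrict_mask = np.ones((h, w), dtype=bool)
    if restrict_mask.shape != (h, w):
        raise ValueError("restrict_mask is not aligned with the working raster")
    out = np.full((h, w), UNCLASSIFIED, dtype=np.int16)
    if restrict_mask.any():
        stack = compute_feature_stack(channels, model.feature_config)
        rr, cc = np.nonzero(restrict_mask)
        proba = model.forest.predict_proba(stack.at(rr, cc))
        # forest classes_ are the declared indices in sorted (= declared) order;
        # np.argmax resolves ties toward the first declared class
        order = np.argsort(model.forest.classes_)
        out[rr, cc] = model.forest.classes_[order][np.argmax(proba[:, order], axis=1)]
    return LabelMask(
        data=out, classes=model.classes, pixel_size_um=image.pixel_size_um
    )


def _upsample_mask(mask: np.ndarray, factor: int, shape: tuple[int, int]) -> np.ndarray:
    up = np.kron(mask, np.ones((factor, factor), dtype=bool))
    out = np.zeros(shape, dtype=bool)
    h = min(shape[0], up.shape[0])
    w = min(shape[1], up.shape[1])
    out[:h, :w] = up[:h, :w]
    return out


@dataclass
class PipelineResult:
    """Per-step masks (at their working resolutions), objects and areas."""

    masks: dict[str, tuple[np.ndarray, float]]
    objects: dict[str, RegionObjects]
    areas_um2: dict[str, float]
    step2_labels: LabelMask | None = None
    step3_labels: LabelMask | None = None


def run_three_step_pipeline(
    image: CalibratedImage,
    threshold_cfg: ThresholdConfig,
    step2_model: TrainedPixelClassifier,
    step3_model: TrainedPixelClassifier,
    object_params: dict | None = None,
) -> PipelineResult:
    """Tissue → mucosa → epithelium, each stage inside the previous one.

    Step 1 thresholds tissue and creates objects (minimum object 10,000 µm²,
    minimum hole 100,000 µm²); step 2 classifies inside the tissue objects
    and creates mucosa objects with the same parameters; step 3 classifies
    inside the mucosa objects at the finer resolution with minimum object
    and hole sizes of 1,000 µm². Object rasters are clipped to their parent
    mask after cleaning, so the containment chain
    epithelium/lamina ⊆ mucosa ⊆ tissue is exact by construction.
    """
    op = {
        "step1_min_object_um2": STEP1_MIN_OBJECT_UM2,
        "step1_min_hole_um2": STEP1_MIN_HOLE_UM2,
        "step3_min_object_um2": STEP3_MIN_OBJECT_UM2,
        "step3_min_hole_um2": STEP3_MIN_HOLE_UM2,
        **(object_params or {}),
    }

    # --- Step 1: tissue detection
    try:
        mask1 = threshold_tissue(image, threshold_cfg)
        tissue_obj = create_objects(
            mask1,
            op["step1_min_object_um2"],
            op["step1_min_hole_um2"],
            class_name="tissue",
            provenance={"step": 1},
        )
    except Exception as exc:  # pragma: no cover - stage identity on propagation
        raise RuntimeError("pipeline step 1 (tissue detection) failed") from exc
    tissue_mask = tissue_obj.mask
    coarse_px = mask1.pixel_size_um

    # --- Step 2: mucosa vs submucosa/muscularis inside the tissue objects
    try:
        img2 = (
            resample(image, step2_model.feature_config.working_resolution_um)
            if image.pixel_size_um
            < step2_model.feature_config.working_resolution_um - 1e-9
            else image
        )
        labels2 = apply_classifier(step2_model, img2, restrict_mask=tissue_mask)
        mucosa_idx = labels2.index_of("mucosa")
        sub_idx = labels2.index_of("submucosa_muscularis")
        mucosa_obj = create_objects(
            labels2.data == mucosa_idx,
            op["step1_min_object_um2"],
            op["step1_min_hole_um2"],
            pixel_size_um=coarse_px,
            class_name="mucosa",
            clip_mask=tissue_mask,
            provenance={"step": 2},
        )
        sub_obj = create_objects(
            labels2.data == sub_idx,
            op["step1_min_object_um2"],
            op["step1_min_hole_um2"],
            pixel_size_um=coarse_px,
            class_name="submucosa_muscularis",
            clip_mask=tissue_mask & ~mucosa_obj.mask,
            provenance={"step": 2},
        )
    except Exception as exc:
        raise RuntimeError("pipeline step 2 (mucosal segmentation) failed") from exc
    mucosa_mask = mucosa_obj.mask

    # --- Step 3: epithelium vs lamina propria inside the mucosa objects
    try:
        fine_res = step3_model.feature_config.working_resolution_um
        img3 = (
            resample(image, fine_res)
            if image.pixel_size_um < fine_res - 1e-9
            else image
        )
        factor = int(round(coarse_px / fine_res))
        restrict3 = _upsample_mask(mucosa_mask, factor, img3.shape)
        labels3 = apply_classifier(step3_model, img3, restrict_mask=restrict3)
        epi_idx = labels3.index_of("epithelium")
        lam_idx = labels3.index_of("lamina_propria")
        epi_obj = create_objects(
            labels3.data == epi_idx,
            op["step3_min_object_um2"],
            op["step3_min_hole_um2"],
            pixel_size_um=fine_res,
            class_name="epithelium",
            clip_mask=restrict3,
            provenance={"step": 3},
        )
        lam_obj = create_objects(
            labels3.data == lam_idx,
            op["step3_min_object_um2"],
            op["step3_min_hole_um2"],
            pixel_size_um=fine_res,
            class_name="lamina_propria",
            clip_mask=restrict3 & ~epi_obj.mask,
            provenance={"step": 3},
        )
    except Exception as exc:
        raise RuntimeError("pipeline step 3 (epithelial segmentation) failed") from exc

    coarse_area = coarse_px**2
    fine_area = fine_res**2
    masks = {
        "tissue": (tissue_mask, coarse_px),
        "mucosa": (mucosa_mask, coarse_px),
        "submucosa_muscularis": (sub_obj.mask, coarse_px),
        "epithelium": (epi_obj.mask, fine_res),
        "lamina_propria": (lam_obj.mask, fine_res),
    }
    areas = {
        "tissue": float(tissue_mask.sum()) * coarse_area,
        "mucosa": float(mucosa_mask.sum()) * coarse_area,
        "submucosa_muscularis": float(sub_obj.mask.sum()) * coarse_area,
        "epithelium": float(epi_obj.mask.sum()) * fine_area,
        "lamina_propria": float(lam_obj.mask.sum()) * fine_area,
    }
    objects = {
        "tissue": tissue_obj,
        "mucosa": mucosa_obj,
        "submucosa_muscularis": sub_obj,
        "epithelium": epi_obj,
        "lamina_propria": lam_obj,
    }
    return PipelineResult(
        masks=masks,
        objects=objects,
        areas_um2=areas,
        step2_labels=labels2,
        step3_labels=labels3,
    )


__all__ = [
    "DEFAULT_RF_PARAMS",
    "STEP2_FEATURES",
    "STEP3_FEATURES",
    "TrainedPixelClassifier",
    "PipelineResult",
    "prepare_channels",
    "train_classifier",
    "apply_classifier",
    "run_three_step_pipeline",
]
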