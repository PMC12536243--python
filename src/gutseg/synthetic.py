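"""Synthetic H&E-like small-intestine sections with exact ground truth.

The generator emulates a full-wall section of piglet small intestine as seen
in a calibrated brightfield scan: a white lumen at the top, a villous mucosa
(columnar epithelial rim over a lamina-propria core) rising from a crypt
band, and submucosal plus muscular layers below. Images are rendered through
a two-stain Beer–Lambert model — per-class hematoxylin/eosin concentrations
mixed through per-image jittered stain vectors — so the stain-estimation
module has something real to recover. Ground truth is exact by construction:
every pixel carries exactly one class from {background, epithelium,
lamina_propria, submucosa_muscularis, lumen_content}.

Age groups (4, 14, 25, 49, 67 days) map to morphology: younger animals get
tighter villus packing and a larger fraction of pale, fetal-type vacuolated
enterocytes along the epithelium — the main driver of age-dependent
segmentation difficulty. Injectable artifact classes reproduce the error
modes seen on real slides: stained luminal debris (non-tissue that looks
like tissue), dilated unstained vessels in the submucosa (tissue that looks
like background), and debris-filled crypt abscesses (lumen content inside
the mucosa). No attempt is made at histologic realism beyond layer
topology, colour, and texture scale; the downstream pipeline consumes
statistics, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import downsample_labels
from .image import (
    GROUND_TRUTH_CLASSES,
    AnnotationSet,
    CalibratedImage,
    LabelMask,
    Stroke,
)
from .stain import DEFAULT_EOSIN, DEFAULT_HEMATOXYLIN

BACKGROUND, EPITHELIUM, LAMINA_PROPRIA, SUBMUCOSA_MUSCULARIS, LUMEN_CONTENT = range(5)

AGE_GROUPS = (4, 14, 25, 49, 67)

#: age → (vacuolation fraction of epithelial extent, inter-villus gap µm);
#: younger animals have more fetal-type vacuolated enterocytes and tighter
#: villus packing
AGE_DEFAULTS: dict[int, tuple[float, float]] = {
    4: (0.50, 18.0),
    14: (0.30, 25.0),
    25: (0.12, 32.0),
    49: (0.04, 39.0),
    67: (0.00, 46.0),
}

#: per-class (hematoxylin, eosin) concentrations of the rendering model
CLASS_CONCENTRATIONS = {
    "background": (0.005, 0.003),
    "epithelium": (0.55, 0.25),
    "lamina_propria": (0.18, 0.22),
    "submucosa": (0.08, 0.24),
    "muscularis": (0.20, 0.45),
    "vacuolated": (0.18, 0.10),
    "goblet": (0.15, 0.08),
    "debris": (0.25, 0.30),
    "abscess": (0.30, 0.25),
    "vessel": (0.004, 0.002),
    "nucleus_boost": (0.45, 0.05),
}

#: layer band thicknesses, µm (muscularis, submucosa, crypt/lamina-propria)
MUSCULARIS_UM = 245.0
SUBMUCOSA_UM = 315.0
CRYPT_BAND_UM = 245.0


@dataclass(frozen=True)
class ArtifactFlags:
    luminal_debris: bool = False
    edema_vessels: bool = False
    crypt_abscesses: bool = False

    def any(self) -> bool:
        return self.luminal_debris or self.edema_vessels or self.crypt_abscesses


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunables of one synthetic section.

    ``vacuolation_fraction`` and ``inter_villus_gap_um`` default to the age
    group's values; set them explicitly to override.
    """

    image_size_px: tuple[int, int] = (448, 448)
    pixel_size_um: float = 3.51
    age_group: int = 49
    villus_count: int | None = None
    villus_length_um: float = 380.0
    villus_width_um: float = 120.0
    inter_villus_gap_um: float | None = None
    vacuolation_fraction: float | None = None
    goblet_density: float = 8.0  # goblet cells per mm of epithelial surface
    epithelial_band_um: float = 32.0
    artifact_flags: ArtifactFlags = field(default_factory=ArtifactFlags)
    color_noise_sd: float = 4.0
    hue_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        for name in ("pixel_size_um", "villus_length_um", "villus_width_um",
                     "epithelial_band_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.vacuolation_fraction is not None and not (
            0.0 <= self.vacuolation_fraction <= 1.0
        ):
            raise ValueError("vacuolation_fraction must lie in [0, 1]")
        if self.inter_villus_gap_um is not None and self.inter_villus_gap_um <= 0:
            raise ValueError("inter_villus_gap_um must be strictly positive")
        if self.goblet_density < 0 or self.color_noise_sd < 0:
            raise ValueError("densities and noise levels must be non-negative")

    def resolved(self) -> "GeneratorConfig":
        """Fill age-dependent defaults into explicit values."""
        vac, gap = AGE_DEFAULTS[self.age_group]
        return replace(
            self,
            vacuolation_fraction=(
                vac if self.vacuolation_fraction is None else self.vacuolation_fraction
            ),
            inter_villus_gap_um=(
                gap if self.inter_villus_gap_um is None else self.inter_villus_gap_um
            ),
        )


@dataclass
class GroundTruth:
    """Exact per-pixel labels plus derived compartment masks."""

    label_mask: LabelMask
    epithelial_band_um: float

    @property
    def tissue_mask(self) -> np.ndarray:
        """Tissue = everything except background and lumen content."""
        return ~self.label_mask.mask_of("background", "lumen_content")

    @property
    def mucosa_mask(self) -> np.ndarray:
        return self.label_mask.mask_of("epithelium", "lamina_propria")

    def step2_labels(self, factor: int = 2) -> LabelMask:
        """Two-class (mucosa vs submucosa/muscularis) mask at a coarser grid.

        Majority-vote downsampled; background and lumen content are
        unclassified (-1).
        """
        down = downsample_labels(
            self.label_mask.data, len(self.label_mask.classes), factor
        )
        out = np.full(down.shape, -1, dtype=np.int16)
        out[(down == EPITHELIUM) | (down == LAMINA_PROPRIA)] = 0
        out[down == SUBMUCOSA_MUSCULARIS] = 1
        return LabelMask(
            data=out,
            classes=("mucosa", "submucosa_muscularis"),
            pixel_size_um=self.label_mask.pixel_size_um * factor,
        )

    def step3_labels(self) -> LabelMask:
        """Two-class (epithelium vs lamina propria) mask at native resolution."""
        src = self.label_mask.data
        out = np.full(src.shape, -1, dtype=np.int16)
        out[src == EPITHELIUM] = 0
        out[src == LAMINA_PROPRIA] = 1
        return LabelMask(
            data=out,
            classes=("epithelium", "lamina_propria"),
            pixel_size_um=self.label_mask.pixel_size_um,
        )


@dataclass
class ArtifactEntry:
    kind: str
    row: int
    col: int
    area_um2: float


@dataclass
class ArtifactRecord:
    entries: list[ArtifactEntry] = field(default_factory=list)

    def count(self, kind: str | None = None) -> int:
        return sum(1 for e in self.entries if kind is None or e.kind == kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"kind": e.kind, "row": e.row, "col": e.col, "area_um2": e.area_um2}
                for e in self.entries
            ],
            columns=["kind", "row", "col", "area_um2"],
        )


# ---------------------------------------------------------------------------
# rendering helpers


def _texture_field(rng: np.random.Generator, shape, sigma: float, amplitude: float):
    g = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    sd = g.std()
    if sd > 0:
        g /= sd
    return np.clip(1.0 + amplitude * g, 0.6, 1.4)


def _jittered_vectors(rng: np.random.Generator, sd: float):
    def jitter(v):
        out = np.clip(v + rng.normal(0.0, sd, 3), 1e-3, None)
        return out / np.linalg.norm(out)

    return jitter(DEFAULT_HEMATOXYLIN), jitter(DEFAULT_EOSIN)


def _compose_rgb(c_h, c_e, v_h, v_e, noise_sd, rng) -> np.ndarray:
    od = c_h[..., None] * v_h + c_e[..., None] * v_e
    rgb = 255.0 * np.power(10.0, -od)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, rgb.shape)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def _disc(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return x * x + y * y <= r * r


# ---------------------------------------------------------------------------
# geometry


def _build_labels(cfg: GeneratorConfig, rng: np.random.Generator):
    """Label raster plus render-modifier masks (vacuolated, goblet, nuclei)."""
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    musc = int(round(MUSCULARIS_UM / px))
    sub = int(round(SUBMUCOSA_UM / px))
    crypt = int(round(CRYPT_BAND_UM / px))
    vlen = cfg.villus_length_um / px
    vhalf = max(2, int(round(cfg.villus_width_um / (2 * px))))
    gap = max(1, int(round(cfg.inter_villus_gap_um / px)))
    band_px = cfg.epithelial_band_um / px

    base_top = h - musc - sub - crypt  # first row of the crypt band
    tip_margin = int(round(1.15 * vlen)) + vhalf + 8
    if base_top < tip_margin:
        raise ValueError(
            f"image height {h}px cannot hold one villus plus the wall layers "
            f"at {px} µm/px (needs ≥ {tip_margin + musc + sub + crypt}px)"
        )

    pitch = 2 * vhalf + gap
    n_villi = cfg.villus_count if cfg.villus_count is not None else max(1, w // pitch)
    if n_villi * (2 * vhalf) + 2 > w:
        raise ValueError(
            f"image width {w}px too small for {n_villi} villi of "
            f"{cfg.villus_width_um} µm at {px} µm/px"
        )

    labels = np.zeros((h, w), dtype=np.int16)
    labels[h - musc :, :] = SUBMUCOSA_MUSCULARIS
    labels[h - musc - sub : h - musc, :] = SUBMUCOSA_MUSCULARIS
    labels[base_top : h - musc - sub, :] = LAMINA_PROPRIA
    muscularis_zone = np.zeros((h, w), dtype=bool)
    muscularis_zone[h - musc :, :] = True

    # capsule-shaped villi on a regular pitch with small jitter
    offset = (w - n_villi * pitch) // 2 + pitch // 2
    yy, xx = np.mgrid[0:h, 0:w]
    for k in range(n_villi):
        cx = offset + k * pitch + rng.integers(-2, 3)
        lk = vlen * (1.0 + rng.uniform(-0.12, 0.12))
        tip_row = base_top - lk + vhalf
        shaft = (np.abs(xx - cx) <= vhalf) & (yy >= tip_row) & (yy < base_top)
        cap = (xx - cx) ** 2 + (yy - tip_row) ** 2 <= vhalf**2
        labels[shaft | cap] = LAMINA_PROPRIA

    # epithelial rim: mucosa pixels within the band distance of the lumen
    dist_to_lumen = ndimage.distance_transform_edt(labels != BACKGROUND)
    mucosa = labels == LAMINA_PROPRIA
    epi = mucosa & (dist_to_lumen <= band_px)
    labels[epi] = EPITHELIUM

    # fetal-type vacuolated enterocytes: the distal (luminal) fraction of the
    # epithelium, selected by row quantile so the pixel fraction matches
    vac_mask = np.zeros((h, w), dtype=bool)
    frac = float(cfg.vacuolation_fraction)
    if frac > 0:
        rows = np.nonzero(labels == EPITHELIUM)[0]
        cutoff = np.quantile(rows, frac)
        vac_mask = (labels == EPITHELIUM) & (yy <= cutoff)

    # goblet cells: pale discs seeded on the epithelial surface at the
    # configured linear density
    goblet_mask = np.zeros((h, w), dtype=bool)
    if cfg.goblet_density > 0:
        surface = (labels == EPITHELIUM) & (
            ndimage.binary_dilation(labels == BACKGROUND) | (dist_to_lumen <= 2)
        )
        n_surface = int(surface.sum())
        length_mm = n_surface * px / 1000.0
        n_goblet = int(round(cfg.goblet_density * length_mm))
        cand = np.argwhere(labels == EPITHELIUM)
        if n_goblet > 0 and len(cand):
            idx = rng.choice(len(cand), size=min(n_goblet, len(cand)), replace=False)
            canvas = np.zeros((h, w), dtype=bool)
            canvas[cand[idx, 0], cand[idx, 1]] = True
            goblet_mask = ndimage.binary_dilation(canvas, structure=_disc(2)) & (
                labels == EPITHELIUM
            )

    # lamina-propria nuclear speckle
    nuclei = (rng.random((h, w)) < 0.05) & (labels == LAMINA_PROPRIA)
    nuclei = ndimage.binary_dilation(nuclei, structure=_disc(1)) & (
        labels == LAMINA_PROPRIA
    )
    return labels, muscularis_zone, vac_mask, goblet_mask, nuclei


def _render(cfg, labels, muscularis_zone, vac_mask, goblet_mask, nuclei, rng):
    h, w = labels.shape
    c_h = np.empty((h, w))
    c_e = np.empty((h, w))

    def paint(mask, key):
        ch, ce = CLASS_CONCENTRATIONS[key]
        c_h[mask] = ch
        c_e[mask] = ce

    paint(labels == BACKGROUND, "background")
    paint(labels == EPITHELIUM, "epithelium")
    paint(labels == LAMINA_PROPRIA, "lamina_propria")
    paint((labels == SUBMUCOSA_MUSCULARIS) & ~muscularis_zone, "submucosa")
    paint((labels == SUBMUCOSA_MUSCULARIS) & muscularis_zone, "muscularis")
    paint(vac_mask, "vacuolated")
    paint(goblet_mask, "goblet")
    nb = CLASS_CONCENTRATIONS["nucleus_boost"]
    c_h[nuclei] += nb[0]
    c_e[nuclei] += nb[1]

    # oriented fibre texture in the muscular layer (banding across rows)
    yy = np.arange(h)[:, None]
    phase = rng.uniform(0, 2 * np.pi)
    fibres = 0.08 * np.sin(2 * np.pi * yy / 9.0 + phase) * np.ones((1, w))
    c_e = np.where(muscularis_zone, c_e + fibres, c_e)

    tissue = labels != BACKGROUND
    c_h = np.where(tissue, c_h * _texture_field(rng, (h, w), 6.0, 0.08), c_h)
    c_e = np.where(tissue, c_e * _texture_field(rng, (h, w), 6.0, 0.08), c_e)

    v_h, v_e = _jittered_vectors(rng, cfg.hue_jitter_sd)
    rgb = _compose_rgb(c_h, c_e, v_h, v_e, cfg.color_noise_sd, rng)
    return rgb, (v_h, v_e)


# ---------------------------------------------------------------------------
# public operations


def generate_tissue_image(
    config: GeneratorConfig,
) -> tuple[CalibratedImage, GroundTruth, ArtifactRecord]:
    """Render one calibrated section with exact ground truth.

    Deterministic for a fixed seed. Artifact-free background pixels always
    have mean RGB above the tissue-detection cutoff of 205, and the five
    class colour/texture distributions are pairwise separable by design (see
    ``CLASS_CONCENTRATIONS``). Raises if the image cannot hold one villus
    plus the wall layers at the configured scale.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    labels, musc_zone, vac, goblet, nuclei = _build_labels(cfg, rng)
    rgb, stain_vectors = _render(cfg, labels, musc_zone, vac, goblet, nuclei, rng)
    image = CalibratedImage(rgb, cfg.pixel_size_um)
    truth = GroundTruth(
        label_mask=LabelMask(labels, GROUND_TRUTH_CLASSES, cfg.pixel_size_um),
        epithelial_band_um=cfg.epithelial_band_um,
    )
    artifact_seed = int(rng.integers(0, 2**31 - 1))
    image, record = inject_artifacts(
        image, truth, cfg.artifact_flags, artifact_seed, stain_vectors=stain_vectors
    )
    return image, truth, record


def inject_artifacts(
    image: CalibratedImage,
    truth: GroundTruth,
    flags: ArtifactFlags,
    seed: int,
    stain_vectors: tuple[np.ndarray, np.ndarray] | None = None,
    noise_sd: float = 4.0,
) -> tuple[CalibratedImage, ArtifactRecord]:
    """Paint the configured artifact classes into an existing section.

    Ground-truth labels are updated in place where the artifact convention
    demands it: luminal debris and crypt abscesses become ``lumen_content``
    (not tissue, not mucosa); dilated vessels stay ``submucosa_muscularis``
    (unstained tissue). Pixels outside each artifact's target compartment
    are never modified. With all flags false the input image is returned
    unchanged with an empty record.
    """
    if truth.label_mask.shape != image.shape:
        raise ValueError("ground truth is not aligned with the image")
    record = ArtifactRecord()
    if not flags.any():
        return image, record

    rng = np.random.default_rng(seed)
    v_h, v_e = stain_vectors if stain_vectors is not None else (
        DEFAULT_HEMATOXYLIN,
        DEFAULT_EOSIN,
    )
    labels = truth.label_mask.data
    px_area = image.pixel_area_um2
    rgb = image.pixels.copy()
    h, w = labels.shape

    def paint_blob(mask: np.ndarray, key: str) -> None:
        ch0, ce0 = CLASS_CONCENTRATIONS[key]
        n = int(mask.sum())
        c_h = ch0 * (1.0 + rng.normal(0, 0.10, n))
        c_e = ce0 * (1.0 + rng.normal(0, 0.10, n))
        od = c_h[:, None] * v_h + c_e[:, None] * v_e
        vals = 255.0 * np.power(10.0, -od) + rng.normal(0, noise_sd, (n, 3))
        rgb[mask] = np.clip(np.round(vals), 0, 255).astype(np.uint8)

    if flags.luminal_debris:
        lumen_depth = ndimage.distance_transform_edt(labels == BACKGROUND)
        for _ in range(int(rng.integers(2, 5))):
            r = int(rng.integers(8, 17))
            cand = np.argwhere(lumen_depth >= r + 3)
            if not len(cand):
                break
            cy, cx = cand[rng.integers(len(cand))]
            yy, xx = np.ogrid[0:h, 0:w]
            ry = r * rng.uniform(0.7, 1.3)
            blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / r) ** 2 <= 1.0
            blob &= labels == BACKGROUND
            if not blob.any():
                continue
            paint_blob(blob, "debris")
            labels[blob] = LUMEN_CONTENT
            record.entries.append(
                ArtifactEntry("luminal_debris", int(cy), int(cx), blob.sum() * px_area)
            )

    if flags.edema_vessels:
        # one dilated, unstained vessel in the submucosa, large enough to
        # survive the Step-1 minimum-hole rule (> 100,000 µm²)
        musc = int(round(MUSCULARIS_UM / image.pixel_size_um))
        sub = int(round(SUBMUCOSA_UM / image.pixel_size_um))
        ry = max(8, int(0.42 * sub))
        rx = int(np.ceil(1.25 * 100_000.0 / (np.pi * ry * px_area)))
        cy = h - musc - sub // 2
        cx = int(rng.integers(rx + 6, max(rx + 7, w - rx - 6)))
        yy, xx = np.ogrid[0:h, 0:w]
        vessel = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        vessel &= labels == SUBMUCOSA_MUSCULARIS
        if vessel.any():
            paint_blob(vessel, "vessel")
            # ground truth unchanged: an empty vessel is still tissue
            record.entries.append(
                ArtifactEntry("edema_vessel", int(cy), int(cx), vessel.sum() * px_area)
            )

    if flags.crypt_abscesses:
        lp_depth = ndimage.distance_transform_edt(labels == LAMINA_PROPRIA)
        for _ in range(int(rng.integers(2, 4))):
            r = int(rng.integers(5, 9))
            cand = np.argwhere(lp_depth >= r + 2)
            if not len(cand):
                break
            cy, cx = cand[rng.integers(len(cand))]
            yy, xx = np.ogrid[0:h, 0:w]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            blob &= labels == LAMINA_PROPRIA
            if not blob.any():
                continue
            paint_blob(blob, "abscess")
            labels[blob] = LUMEN_CONTENT
            record.entries.append(
                ArtifactEntry("crypt_abscess", int(cy), int(cx), blob.sum() * px_area)
            )

    return CalibratedImage(rgb, image.pixel_size_um), record


def sample_annotations(
    truth: LabelMask,
    classes: tuple[str, ...],
    strokes_per_class: int | dict[str, int],
    stroke_radius_um: float,
    seed: int,
    steps_per_stroke: tuple[int, int] = (18, 40),
) -> AnnotationSet:
    """Draw brush-style training strokes inside ground-truth class regions.

    Each stroke is a disc-swept random-walk path whose every pixel carries
    the requested ground-truth label (the walk is confined to the class
    region eroded by the brush radius, so the swept disc never leaves the
    region). Raises if a class region is too small to contain a stroke of
    the requested radius. Stroke counts and positions are reproducible from
    the seed.
    """
    rng = np.random.default_rng(seed)
    radius_px = max(1, int(round(stroke_radius_um / truth.pixel_size_um)))
    disc = _disc(radius_px)
    out = AnnotationSet(pixel_size_um=truth.pixel_size_um)
    for class_name in classes:
        n_strokes = (
            strokes_per_class[class_name]
            if isinstance(strokes_per_class, dict)
            else strokes_per_class
        )
        if n_strokes == 0:
            continue
        region = truth.mask_of(class_name)
        if not region.any():
            raise ValueError(f"class {class_name!r} is absent from the ground truth")
        # erosion by the brush disc, via the Euclidean distance transform:
        # a disc of radius r centred at p stays inside iff dist(p, ~region) > r
        eroded = ndimage.distance_transform_edt(region) > radius_px
        allowed = np.argwhere(eroded)
        if not len(allowed):
            raise ValueError(
                f"region {class_name!r} is too small for a brush of radius "
                f"{stroke_radius_um} µm"
            )
        allowed_set = np.zeros(region.shape, dtype=bool)
        allowed_set[allowed[:, 0], allowed[:, 1]] = True
        for _ in range(n_strokes):
            start = allowed[rng.integers(len(allowed))]
            path = [tuple(start)]
            cur = tuple(start)
            n_steps = int(rng.integers(*steps_per_stroke))
            for _ in range(n_steps):
                nbrs = [
                    (cur[0] + dy, cur[1] + dx)
                    for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1)
                    if (dy, dx) != (0, 0)
                    and 0 <= cur[0] + dy < region.shape[0]
                    and 0 <= cur[1] + dx < region.shape[1]
                    and allowed_set[cur[0] + dy, cur[1] + dx]
                ]
                if not nbrs:
                    break
                cur = nbrs[rng.integers(len(nbrs))]
                path.append(cur)
            canvas = np.zeros(region.shape, dtype=bool)
            pr, pc = zip(*path)
            canvas[list(pr), list(pc)] = True
            swept = ndimage.binary_dilation(canvas, structure=disc)
            rr, cc = np.nonzero(swept)
            out.strokes.append(Stroke(class_name=class_name, rows=rr, cols=cc))
    return out


@dataclass
class CohortSample:
    sample_id: str
    age_group: int
    image: CalibratedImage
    truth: GroundTruth
    artifacts: ArtifactRecord
    config: GeneratorConfig


def generate_cohort(
    n_per_age_group: int,
    config_overrides: dict | None = None,
    seed: int = 0,
) -> list[CohortSample]:
    """Generate ``n_per_age_group`` samples for each of the five age groups.

    Per-sample seeds follow the counter scheme
    ``(seed * 100_000 + index) % 2**31`` with ``index`` running over samples
    in age order, so cohorts are reproducible element-wise. Unless fixed via
    ``config_overrides``, villus length and width are jittered per sample
    (±20% / ±10%) to emulate inter-animal morphological variation, so
    section areas genuinely vary across the cohort.
    """
    if n_per_age_group < 1:
        raise ValueError("n_per_age_group must be at least 1")
    overrides = dict(config_overrides or {})
    overrides.pop("seed", None)
    base = GeneratorConfig()
    cohort: list[CohortSample] = []
    index = 0
    for age in AGE_GROUPS:
        for k in range(n_per_age_group):
            sample_seed = (seed * 100_000 + index) % 2**31
            morph = np.random.default_rng((sample_seed + 17) % 2**31)
            per_sample = dict(overrides)
            if "villus_length_um" not in per_sample:
                per_sample["villus_length_um"] = round(
                    base.villus_length_um * morph.uniform(0.8, 1.2), 1
                )
            if "villus_width_um" not in per_sample:
                per_sample["villus_width_um"] = round(
                    base.villus_width_um * morph.uniform(0.9, 1.1), 1
                )
            cfg = GeneratorConfig(age_group=age, seed=sample_seed, **per_sample)
            image, truth, record = generate_tissue_image(cfg)
            cohort.append(
                CohortSample(
                    sample_id=f"age{age:02d}_{k:03d}",
                    age_group=age,
                    image=image,
                    truth=truth,
                    artifacts=record,
                    config=cfg,
                )
            )
            index += 1
    return cohort
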