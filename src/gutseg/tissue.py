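"""Tissue detection and the shared classification-to-objects machinery.

Step 1 of the pipeline classifies tissue against background by thresholding
the Gaussian-smoothed mean-RGB image at its working resolution (7.03 µm/px,
sigma 2.0, cutoff 205; pixels strictly below the cutoff are tissue). The
classification is then converted to measurable polygonal objects: connected
components smaller than a minimum object size are discarded and interior
holes smaller than a minimum hole size are filled, so that small unstained
spaces (vessels, edema) do not fragment the tissue region. The same object
machinery serves the mucosal and epithelial stages.

Conventions: objects are 8-connected and holes 4-connected; a pixel whose
smoothed mean RGB equals the threshold exactly is background; components and
holes exactly at the printed minimum sizes are kept/preserved ("below"
removes, strictly). Region outlines are traced with marching squares at the
0.5 level and areas computed by the shoelace formula (via shapely).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure, morphology

from .features import resample
from .image import CalibratedImage, LabelMask

TISSUE_THRESHOLD = 205.0
STEP1_WORKING_RESOLUTION_UM = 7.03
STEP1_SMOOTHING_SIGMA = 2.0
STEP1_MIN_OBJECT_UM2 = 10_000.0
STEP1_MIN_HOLE_UM2 = 100_000.0
STEP3_MIN_OBJECT_UM2 = 1_000.0
STEP3_MIN_HOLE_UM2 = 1_000.0


@dataclass(frozen=True)
class ThresholdConfig:
    working_resolution_um: float = STEP1_WORKING_RESOLUTION_UM
    smoothing_sigma: float = STEP1_SMOOTHING_SIGMA
    threshold: float = TISSUE_THRESHOLD
    below_is_tissue: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 255.0):
            raise ValueError("threshold must lie in (0, 255)")
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be strictly positive")


@dataclass
class Region:
    class_name: str
    polygon: Polygon  # coordinates in µm
    area_um2: float


@dataclass
class RegionObjects:
    """Polygonal regions plus the cleaned binary raster they were traced from."""

    regions: list[Region] = field(default_factory=list)
    mask: np.ndarray | None = None
    pixel_size_um: float = 1.0
    provenance: dict = field(default_factory=dict)

    def total_area_um2(self, class_name: str | None = None) -> float:
        return float(
            sum(
                r.area_um2
                for r in self.regions
                if class_name is None or r.class_name == class_name
            )
        )


def threshold_tissue(
    image: CalibratedImage, cfg: ThresholdConfig = ThresholdConfig()
) -> LabelMask:
    """Classify tissue vs background on the smoothed mean-RGB image.

    The image is resampled to the working resolution if finer, the mean of
    the three colour channels is Gaussian-smoothed, and pixels strictly
    below the threshold are tissue (inverted when ``below_is_tissue`` is
    False). Deterministic.
    """
    if image.pixel_size_um < cfg.working_resolution_um - 1e-9:
        image = resample(image, cfg.working_resolution_um)
    smoothed = ndimage.gaussian_filter(
        image.mean_rgb(), cfg.smoothing_sigma, mode="reflect"
    )
    tissue = smoothed < cfg.threshold
    if not cfg.below_is_tissue:
        tissue = ~tissue
    return LabelMask(
        data=tissue.astype(np.int16),
        classes=("background", "tissue"),
        pixel_size_um=image.pixel_size_um,
    )


def clean_mask(
    mask: np.ndarray,
    pixel_size_um: float,
    min_object_um2: float,
    min_hole_um2: float,
) -> np.ndarray:
    """Remove components below the object minimum, then fill holes below the
    hole minimum. Sizes exactly at a minimum survive."""
    px_area = pixel_size_um**2
    min_obj_px = int(np.ceil(min_object_um2 / px_area))
    # fill holes with area_px * px_area < min_hole_um2
    hole_px = int(np.ceil(min_hole_um2 / px_area)) - 1
    out = np.asarray(mask, dtype=bool)
    # max_size semantics: removes components of size <= max_size
    if min_obj_px > 1:
        out = morphology.remove_small_objects(out, max_size=min_obj_px - 1, connectivity=2)
    if hole_px > 0:
        # a hole is a 4-connected background component NOT touching the border
        lab, n = ndimage.label(~out)
        if n:
            border_ids = np.unique(
                np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
            )
            sizes = np.bincount(lab.ravel())
            fill = np.zeros(n + 1, dtype=bool)
            fill[1:] = sizes[1:] <= hole_px
            fill[border_ids] = False
            out = out | fill[lab]
    return out


def _contours_to_polygons(mask: np.ndarray, pixel_size_um: float) -> list[Polygon]:
    """Marching-squares outlines of a binary raster as shapely polygons in µm.

    Outer boundaries become shells; contours contained in a shell become its
    holes (holes in holes start new shells, handled recursively by area
    ordering).
    """
    padded = np.pad(mask.astype(np.float64), 1)
    contours = measure.find_contours(padded, 0.5)
    rings = []
    for c in contours:
        coords = (c - 1.0) * pixel_size_um  # unpad, scale; (row, col) order
        poly = Polygon(np.column_stack([coords[:, 1], coords[:, 0]]))
        if poly.is_valid and poly.area > 0:
            rings.append(poly)
    rings.sort(key=lambda p: p.area, reverse=True)
    shells: list[tuple[Polygon, list]] = []
    for ring in rings:
        placed = False
        for shell, holes in shells:
            if shell.contains(ring):
                inside_hole = any(Polygon(h).contains(ring) for h in holes)
                if not inside_hole:
                    holes.append(list(ring.exterior.coords))
                    placed = True
                    break
                # a ring inside a hole is a new shell (island)
        if not placed and not any(s.contains(ring) for s, _ in shells):
            shells.append((ring, []))
            placed = True
        if not placed:
            shells.append((ring, []))
    return [Polygon(list(s.exterior.coords), holes) for s, holes in shells]


def create_objects(
    mask: LabelMask | np.ndarray,
    min_object_size_um2: float,
    min_hole_size_um2: float,
    pixel_size_um: float | None = None,
    class_name: str = "tissue",
    clip_mask: np.ndarray | None = None,
    provenance: dict | None = None,
) -> RegionObjects:
    """Convert a binary classification into measurable polygonal objects.

    Accepts either a binary :class:`LabelMask` (positive class = index 1) or
    a boolean array plus ``pixel_size_um``. ``clip_mask`` restricts the
    cleaned raster (applied after cleaning, so hole-filling can never leak
    outside a parent region in the hierarchical pipeline). An empty mask
    yields empty objects, not an error.
    """
    if isinstance(mask, LabelMask):
        binary = mask.data == 1
        px = mask.pixel_size_um
    else:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um is required with a raw array mask")
        binary = np.asarray(mask, dtype=bool)
        px = float(pixel_size_um)
    cleaned = clean_mask(binary, px, min_object_size_um2, min_hole_size_um2)
    if clip_mask is not None:
        cleaned = cleaned & clip_mask
    regions: list[Region] = []
    labeled, n = ndimage.label(cleaned, structure=np.ones((3, 3), dtype=int))
    for i in range(1, n + 1):
        comp = labeled == i
        for poly in _contours_to_polygons(comp, px):
            regions.append(Region(class_name=class_name, polygon=poly, area_um2=poly.area))
    return RegionObjects(
        regions=regions,
        mask=cleaned,
        pixel_size_um=px,
        provenance={
            "min_object_size_um2": min_object_size_um2,
            "min_hole_size_um2": min_hole_size_um2,
            **(provenance or {}),
        },
    )


def measure_area(objects: RegionObjects) -> dict[str, float]:
    """Total polygon area in µm² per class label."""
    out: dict[str, float] = {}
    for r in objects.regions:
        out[r.class_name] = out.get(r.class_name, 0.0) + r.area_um2
    return out


def objects_to_geojson(objects: Iterable[RegionObjects]) -> dict:
    """GeoJSON FeatureCollection with polygon coordinates in µm."""
    from shapely.geometry import mapping

    features = []
    for obj in objects:
        for r in obj.regions:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(r.polygon),
                    "properties": {
                        "class": r.class_name,
                        "area_um2": r.area_um2,
                        **obj.provenance,
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}
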