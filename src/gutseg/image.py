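"""Calibrated raster containers and file I/O.

Everything downstream of the generator is resolution-aware: images and label
masks carry their physical pixel size in micrometres per pixel, and all areas
are reported in µm². Images are written as RGB TIFF with the pixel size in the
TIFF resolution tags and echoed in a YAML sidecar; masks as single-channel
indexed TIFF with the class legend in the sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

UNCLASSIFIED = -1

#: class vocabulary of the synthetic ground truth, in raster index order
GROUND_TRUTH_CLASSES = (
    "background",
    "epithelium",
    "lamina_propria",
    "submucosa_muscularis",
    "lumen_content",
)


@dataclass
class CalibratedImage:
    """An RGB (or single-channel) raster with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W, 3)`` uint8 RGB or ``(H, W)`` float channel raster.
    pixel_size_um : float
        Side length of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2

    def mean_rgb(self) -> np.ndarray:
        """Per-pixel mean of the three colour channels, as float64."""
        if self.pixels.ndim != 3:
            raise ValueError("mean_rgb requires an RGB image")
        return self.pixels.astype(np.float64).mean(axis=2)


@dataclass
class LabelMask:
    """A per-pixel class raster aligned to a :class:`CalibratedImage`.

    ``data`` holds class indices into ``classes``; ``UNCLASSIFIED`` (-1) marks
    pixels outside any class (e.g. outside a restriction mask).
    """

    data: np.ndarray
    classes: tuple[str, ...]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        self.classes = tuple(self.classes)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be strictly positive")
        if self.data.max(initial=UNCLASSIFIED) >= len(self.classes):
            raise ValueError("label raster contains indices outside the class list")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2

    def index_of(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise KeyError(f"class {name!r} not in vocabulary {self.classes}") from None

    def mask_of(self, *names: str) -> np.ndarray:
        """Boolean union mask of the named classes."""
        out = np.zeros(self.data.shape, dtype=bool)
        for name in names:
            out |= self.data == self.index_of(name)
        return out

    def area_um2(self, *names: str) -> float:
        return float(self.mask_of(*names).sum()) * self.pixel_area_um2


@dataclass
class Stroke:
    """One brush stroke: a disc-swept connected path inside a single class."""

    class_name: str
    rows: np.ndarray
    cols: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)


@dataclass
class AnnotationSet:
    """Sparse brush-style training labels over a calibrated raster."""

    strokes: list[Stroke] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __len__(self) -> int:
        return len(self.strokes)

    @property
    def classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.strokes:
            seen.setdefault(s.class_name, None)
        return tuple(seen)

    def n_pixels(self, class_name: str | None = None) -> int:
        return sum(
            s.n_pixels
            for s in self.strokes
            if class_name is None or s.class_name == class_name
        )

    def pixel_indices(self, class_name: str) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated (rows, cols) of every stroke of ``class_name``."""
        rows = [s.rows for s in self.strokes if s.class_name == class_name]
        cols = [s.cols for s in self.strokes if s.class_name == class_name]
        if not rows:
            return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
        return np.concatenate(rows), np.concatenate(cols)


# ---------------------------------------------------------------------------
# file I/O


def _resolution_tag(pixel_size_um: float) -> tuple[float, float]:
    # TIFF resolution is pixels per unit; use centimetres (10,000 µm).
    ppcm = 10_000.0 / pixel_size_um
    return (ppcm, ppcm)


def write_image(path: str | Path, image: CalibratedImage) -> None:
    path = Path(path)
    tifffile.imwrite(
        path,
        np.ascontiguousarray(image.pixels),
        resolution=_resolution_tag(image.pixel_size_um),
        resolutionunit="CENTIMETER",
    )
    sidecar = {"pixel_size_um": float(image.pixel_size_um)}
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_image(path: str | Path) -> CalibratedImage:
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    if sidecar_path.exists():
        meta = yaml.safe_load(sidecar_path.read_text())
        pixel_size = float(meta["pixel_size_um"])
    else:
        with tifffile.TiffFile(path) as tif:
            tags = tif.pages[0].tags
            xres = tags["XResolution"].value
            pixel_size = 10_000.0 * xres[1] / xres[0]
    return CalibratedImage(pixels=pixels, pixel_size_um=pixel_size)


def write_mask(path: str | Path, mask: LabelMask) -> None:
    path = Path(path)
    # shift by +1 so UNCLASSIFIED (-1) maps to 0 in an unsigned raster
    tifffile.imwrite(
        path,
        (mask.data + 1).astype(np.uint8),
        resolution=_resolution_tag(mask.pixel_size_um),
        resolutionunit="CENTIMETER",
    )
    sidecar = {
        "pixel_size_um": float(mask.pixel_size_um),
        "classes": list(mask.classes),
        "encoding": "raster value = class index + 1; 0 = unclassified",
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    raw = tifffile.imread(path).astype(np.int16) - 1
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    return LabelMask(
        data=raw,
        classes=tuple(meta["classes"]),
        pixel_size_um=float(meta["pixel_size_um"]),
    )
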