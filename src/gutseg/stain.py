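"""H&E stain estimation and colour deconvolution.

RGB transmission is converted to optical density (OD) via Beer–Lambert,
``OD = -log10(max(I, 1) / white_point)``, and each pixel's OD triplet is
modelled as a non-negative combination of two unit stain vectors
(hematoxylin and eosin). Stain vectors are refit per image in the Macenko
style: SVD of the tissue-pixel OD cloud, projection onto the dominant
plane, and robust angular percentiles as the two stain directions. The
hematoxylin channel produced here is the extra input channel used by the
mucosal and epithelial pixel classifiers; the eosin channel is computed for
diagnostics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .image import CalibratedImage

#: published default H&E absorbance directions (Ruifrok–Johnston), unit norm
DEFAULT_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
DEFAULT_EOSIN = np.array([0.072, 0.990, 0.105])

#: tissue gate reused from the tissue-detection threshold: mean RGB <= 205
TISSUE_MEAN_RGB_MAX = 205.0

#: minimum tissue pixels required before per-image estimation is attempted
MIN_TISSUE_PIXELS = 200

#: percentile pair defining the robust angular extremes
ANGLE_PERCENTILES = (1.0, 99.0)

#: OD below which a pixel is considered unstained and excluded from the fit
OD_GATE = 0.05

#: minimum angle (degrees) between stain vectors accepted for deconvolution
MIN_STAIN_ANGLE_DEG = 1.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass
class StainModel:
    """Two unit stain vectors in OD space plus the white point.

    ``max_od`` holds a robust (99th percentile) concentration per stain on
    the image the model was fitted to; it is carried as a normalisation
    constant and does not rescale deconvolved channels by default.
    """

    hematoxylin: np.ndarray
    eosin: np.ndarray
    white_point: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )
    max_od: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    is_fallback: bool = False

    def __post_init__(self) -> None:
        self.hematoxylin = _unit(np.asarray(self.hematoxylin, dtype=np.float64))
        self.eosin = _unit(np.asarray(self.eosin, dtype=np.float64))
        self.white_point = np.asarray(self.white_point, dtype=np.float64)
        if np.any(self.hematoxylin < -1e-9) or np.any(self.eosin < -1e-9):
            raise ValueError("stain vectors must have non-negative components")
        if np.any(self.white_point <= 0) or np.any(self.white_point > 255):
            raise ValueError("white point components must lie in (0, 255]")

    @property
    def matrix(self) -> np.ndarray:
        """3x2 mixing matrix with stain vectors as columns (H first)."""
        return np.stack([self.hematoxylin, self.eosin], axis=1)

    def angle_deg(self) -> float:
        c = float(np.clip(self.hematoxylin @ self.eosin, -1.0, 1.0))
        return float(np.degrees(np.arccos(c)))

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "hematoxylin": self.hematoxylin.tolist(),
                "eosin": self.eosin.tolist(),
                "white_point": self.white_point.tolist(),
                "max_od": np.asarray(self.max_od, dtype=float).tolist(),
                "is_fallback": bool(self.is_fallback),
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "StainModel":
        d = yaml.safe_load(text)
        return cls(
            hematoxylin=np.array(d["hematoxylin"]),
            eosin=np.array(d["eosin"]),
            white_point=np.array(d["white_point"]),
            max_od=np.array(d["max_od"]),
            is_fallback=bool(d["is_fallback"]),
        )


def default_stain_model() -> StainModel:
    return StainModel(
        hematoxylin=DEFAULT_HEMATOXYLIN.copy(),
        eosin=DEFAULT_EOSIN.copy(),
        is_fallback=True,
    )


def rgb_to_od(
    image: CalibratedImage | np.ndarray,
    white_point: np.ndarray | tuple[float, float, float] = (255.0, 255.0, 255.0),
) -> np.ndarray:
    """Per-pixel optical density, ``-log10(max(I, 1) / white_point)``.

    Intensities are clamped at 1 before the logarithm so OD stays finite;
    the clamp is part of the contract. OD is non-negative wherever intensity
    does not exceed the white point.
    """
    wp = np.asarray(white_point, dtype=np.float64)
    if np.any(wp <= 0) or np.any(wp > 255):
        raise ValueError("white point components must lie in (0, 255]")
    px = image.pixels if isinstance(image, CalibratedImage) else image
    px = np.asarray(px, dtype=np.float64)
    return -np.log10(np.maximum(px, 1.0) / wp)


def od_to_rgb(od: np.ndarray, white_point=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (float output, no quantisation)."""
    wp = np.asarray(white_point, dtype=np.float64)
    return wp * np.power(10.0, -np.asarray(od, dtype=np.float64))


def estimate_stain_vectors(
    image: CalibratedImage,
    tissue_threshold: float = TISSUE_MEAN_RGB_MAX,
    min_tissue_pixels: int = MIN_TISSUE_PIXELS,
    percentiles: tuple[float, float] = ANGLE_PERCENTILES,
) -> StainModel:
    """Fit per-image H&E stain vectors from tissue-pixel optical densities.

    Macenko-style: stained pixels (mean RGB at or below the tissue gate and
    total OD above a small floor) are projected onto the top-2 right-singular
    plane of their OD cloud; the 1st/99th percentiles of the in-plane angle
    give the two stain directions. Falls back to the published default H&E
    vectors, with ``is_fallback`` set, when too few tissue pixels exist.
    Deterministic and invariant to pixel order.
    """
    od = rgb_to_od(image)
    mean_rgb = image.mean_rgb()
    sel = (mean_rgb <= tissue_threshold) & (od.sum(axis=2) > OD_GATE)
    pts = od[sel]
    if pts.shape[0] < min_tissue_pixels:
        return default_stain_model()

    # dominant OD plane; sign-fix the basis so it is deterministic
    _, _, vt = np.linalg.svd(pts - 0.0, full_matrices=False)
    basis = vt[:2]
    for i in range(2):
        if basis[i].sum() < 0:
            basis[i] = -basis[i]
    proj = pts @ basis.T
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, percentiles)
    v_lo = _unit(np.cos(lo) * basis[0] + np.sin(lo) * basis[1])
    v_hi = _unit(np.cos(hi) * basis[0] + np.sin(hi) * basis[1])
    v_lo = np.clip(v_lo, 0.0, None)
    v_hi = np.clip(v_hi, 0.0, None)
    # hematoxylin absorbs strongly in red; eosin barely does
    if v_lo[0] >= v_hi[0]:
        hem, eos = v_lo, v_hi
    else:
        hem, eos = v_hi, v_lo
    model = StainModel(hematoxylin=hem, eosin=eos)
    conc = _project_concentrations(pts, model)
    model.max_od = np.percentile(conc, 99.0, axis=0)
    return model


def _project_concentrations(od_points: np.ndarray, model: StainModel) -> np.ndarray:
    """Least-squares stain concentrations for an (n, 3) OD point set."""
    m = model.matrix
    pinv = np.linalg.pinv(m)
    return od_points @ pinv.T


def deconvolve(
    image: CalibratedImage, model: StainModel
) -> tuple[CalibratedImage, CalibratedImage]:
    """Unmix an RGB image into hematoxylin and eosin concentration rasters.

    Each pixel's OD is projected onto the model's two stain vectors by least
    squares; negative concentrations are clipped to zero. Returns calibrated
    single-channel float rasters (hematoxylin, eosin). Rejects models whose
    stain vectors are collinear within the angular tolerance.
    """
    if model.angle_deg() < MIN_STAIN_ANGLE_DEG:
        raise ValueError(
            f"stain vectors are collinear ({model.angle_deg():.3f} deg apart); "
            "deconvolution is ill-posed"
        )
    od = rgb_to_od(image, model.white_point)
    flat = od.reshape(-1, 3)
    conc = _project_concentrations(flat, model)
    conc = np.clip(conc, 0.0, None)
    h = conc[:, 0].reshape(od.shape[:2])
    e = conc[:, 1].reshape(od.shape[:2])
    return (
        CalibratedImage(h, image.pixel_size_um),
        CalibratedImage(e, image.pixel_size_um),
    )


def hematoxylin_channel(image: CalibratedImage, model: StainModel | None = None) -> np.ndarray:
    """Convenience: per-image stain fit (unless given) + H concentration."""
    if model is None:
        model = estimate_stain_vectors(image)
    h, _ = deconvolve(image, model)
    return h.pixels


def reconstruct_od(h: np.ndarray, e: np.ndarray, model: StainModel) -> np.ndarray:
    """Forward-mix concentrations back to an OD image (round-trip check)."""
    conc = np.stack([h, e], axis=-1)
    return conc @ model.matrix.T
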