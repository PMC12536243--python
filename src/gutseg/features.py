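"""Per-pixel multiscale feature banks and resolution handling.

The two classifier stages work at fixed physical resolutions: the mucosal
stage at 7.03 µm/px with Gaussian, Laplacian-of-Gaussian, weighted-deviation
and Hessian-determinant features at scales 1.0 and 2.0, and the epithelial
stage at 3.51 µm/px with those plus gradient magnitude and structure-tensor
coherence, all at scale 1.0. Scales are the Gaussian sigma in
working-resolution pixels. All filters use reflect padding so that border
pixels are not darkened relative to the interior.

"Weighted deviation" is the Gaussian-weighted local standard deviation
``sqrt(max(0, G_sigma * I^2 - (G_sigma * I)^2))`` — the running deviation of
intensities under a Gaussian window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .image import CalibratedImage

VALID_CHANNELS = ("R", "G", "B", "hematoxylin")
VALID_FEATURES = (
    "gaussian",
    "laplacian_of_gaussian",
    "weighted_deviation",
    "gradient_magnitude",
    "structure_tensor_coherence",
    "hessian_determinant",
)

#: eigenvalue-sum floor below which coherence is defined as 0
COHERENCE_EPS = 1e-12

BOUNDARY_MODE = "reflect"


@dataclass(frozen=True)
class FeatureConfig:
    """Channels, filter set, scales and working resolution of a feature bank."""

    channels: tuple[str, ...]
    features: tuple[str, ...]
    scales: tuple[float, ...]
    working_resolution_um: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "scales", tuple(float(s) for s in self.scales))
        if not self.channels or not self.features or not self.scales:
            raise ValueError("channels, features and scales must be non-empty")
        for c in self.channels:
            if c not in VALID_CHANNELS:
                raise ValueError(f"unknown channel {c!r}")
        for f in self.features:
            if f not in VALID_FEATURES:
                raise ValueError(f"unknown feature {f!r}")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be strictly positive")
        if self.working_resolution_um <= 0:
            raise ValueError("working_resolution_um must be strictly positive")

    @property
    def n_columns(self) -> int:
        return len(self.channels) * len(self.features) * len(self.scales)

    def column_metadata(self) -> list[tuple[str, str, float]]:
        """Deterministic (channel, feature, scale) tuple per output column."""
        return [
            (c, f, s)
            for c in self.channels
            for f in self.features
            for s in self.scales
        ]

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "channels": list(self.channels),
                "features": list(self.features),
                "scales": list(self.scales),
                "working_resolution_um": float(self.working_resolution_um),
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "FeatureConfig":
        d = yaml.safe_load(text)
        return cls(
            channels=tuple(d["channels"]),
            features=tuple(d["features"]),
            scales=tuple(d["scales"]),
            working_resolution_um=float(d["working_resolution_um"]),
        )


#: mucosal-stage preset: 4 smoothing/texture features at two scales, 7.03 µm/px
STEP2_FEATURES = FeatureConfig(
    channels=("R", "G", "B", "hematoxylin"),
    features=(
        "gaussian",
        "laplacian_of_gaussian",
        "weighted_deviation",
        "hessian_determinant",
    ),
    scales=(1.0, 2.0),
    working_resolution_um=7.03,
)

#: epithelial-stage preset: the full six-feature set at scale 1.0, 3.51 µm/px
STEP3_FEATURES = FeatureConfig(
    channels=("R", "G", "B", "hematoxylin"),
    features=(
        "gaussian",
        "laplacian_of_gaussian",
        "weighted_deviation",
        "gradient_magnitude",
        "structure_tensor_coherence",
        "hessian_determinant",
    ),
    scales=(1.0,),
    working_resolution_um=3.51,
)


@dataclass
class FeatureStack:
    """``(H, W, F)`` feature raster with per-column metadata."""

    data: np.ndarray
    columns: list[tuple[str, str, float]] = field(default_factory=list)
    working_resolution_um: float = 1.0

    def at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Feature matrix (n_pixels, F) at the given raster coordinates."""
        return self.data[rows, cols, :]


# ---------------------------------------------------------------------------
# resampling


def _area_weights(n_in: int, ratio: float) -> np.ndarray:
    """Row-stochastic matrix mapping n_in samples to floor(n_in/ratio) by
    exact interval-overlap (area) weighting."""
    n_out = int(np.floor(n_in / ratio))
    w = np.zeros((n_out, n_in))
    for j in range(n_out):
        lo, hi = j * ratio, (j + 1) * ratio
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n_in)):
            overlap = min(hi, i + 1) - max(lo, i)
            if overlap > 0:
                w[j, i] = overlap
        w[j] /= w[j].sum()
    return w


def resample(image: CalibratedImage, target_um_per_px: float) -> CalibratedImage:
    """Downsample to a coarser physical resolution.

    Integer ratios use exact block averaging; non-integer ratios use
    area-weighted (interval-overlap) averaging. Ratios within 0.5% of an
    integer are treated as that integer, so the printed 3.51 -> 7.03 µm/px
    pair resolves to an exact 2x block mean (the output keeps the requested
    calibration). Upsampling is rejected.
    """
    ratio = target_um_per_px / image.pixel_size_um
    if ratio < 1.0 - 5e-3:
        raise ValueError(
            f"refusing to upsample: target {target_um_per_px} µm/px is finer "
            f"than native {image.pixel_size_um} µm/px"
        )
    if abs(ratio - 1.0) < 5e-3:
        return CalibratedImage(image.pixels.copy(), image.pixel_size_um)
    px = image.pixels.astype(np.float64)
    if abs(ratio - round(ratio)) < 5e-3 * round(ratio):
        k = int(round(ratio))
        h, w = px.shape[:2]
        hh, ww = h // k, w // k
        px = px[: hh * k, : ww * k]
        if px.ndim == 3:
            out = px.reshape(hh, k, ww, k, px.shape[2]).mean(axis=(1, 3))
        else:
            out = px.reshape(hh, k, ww, k).mean(axis=(1, 3))
    else:
        wr = _area_weights(px.shape[0], ratio)
        wc = _area_weights(px.shape[1], ratio)
        if px.ndim == 3:
            out = np.einsum("ri,ick,cj->rjk", wr, px, wc.T)
        else:
            out = wr @ px @ wc.T
    return CalibratedImage(out, target_um_per_px)


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Majority (block-mean >= 0.5) downsampling of a boolean mask."""
    h, w = mask.shape
    hh, ww = h // factor, w // factor
    m = mask[: hh * factor, : ww * factor].astype(np.float64)
    return m.reshape(hh, factor, ww, factor).mean(axis=(1, 3)) >= 0.5


def downsample_labels(labels: np.ndarray, n_classes: int, factor: int) -> np.ndarray:
    """Per-block majority vote over class indices; ties go to the lower index.

    Pixels labelled -1 (unclassified) never win unless the whole block is -1.
    """
    h, w = labels.shape
    hh, ww = h // factor, w // factor
    lab = labels[: hh * factor, : ww * factor]
    counts = np.zeros((hh, ww, n_classes), dtype=np.int32)
    for c in range(n_classes):
        blk = (lab == c).reshape(hh, factor, ww, factor).sum(axis=(1, 3))
        counts[:, :, c] = blk
    out = np.argmax(counts, axis=2).astype(np.int16)
    out[counts.sum(axis=2) == 0] = -1
    return out


# ---------------------------------------------------------------------------
# filters


def gaussian_kernel_1d(sigma: float, order: int = 0, truncate: float = 4.0) -> np.ndarray:
    """Sampled Gaussian kernel (normalised to unit sum) or its derivative.

    The second-derivative kernel is DC-corrected (its truncated sum is
    subtracted out) so that derivative features are exactly zero on constant
    images; the first-derivative kernel is antisymmetric and sums to zero by
    construction.
    """
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=np.float64)
    phi = np.exp(-0.5 * x * x / sigma**2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return phi * (-x / sigma**2)
    if order == 2:
        k = phi * (x * x / sigma**4 - 1.0 / sigma**2)
        # fold the truncation residue into the centre tap so the kernel has
        # exactly zero total weight (constants respond exactly 0)
        k[r] -= k.sum()
        return k
    raise ValueError("derivative order must be 0, 1 or 2")


def _gaussian(img: np.ndarray, sigma: float, order=(0, 0)) -> np.ndarray:
    # convolution (not correlation): reverse each 1-D kernel
    out = ndimage.correlate1d(
        img, gaussian_kernel_1d(sigma, order[0])[::-1], axis=0, mode=BOUNDARY_MODE
    )
    return ndimage.correlate1d(
        out, gaussian_kernel_1d(sigma, order[1])[::-1], axis=1, mode=BOUNDARY_MODE
    )


def gaussian_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    return _gaussian(img, sigma)


def laplacian_of_gaussian(img: np.ndarray, sigma: float) -> np.ndarray:
    return _gaussian(img, sigma, order=(2, 0)) + _gaussian(img, sigma, order=(0, 2))


def weighted_deviation(img: np.ndarray, sigma: float) -> np.ndarray:
    mean = _gaussian(img, sigma)
    mean_sq = _gaussian(img * img, sigma)
    var = mean_sq - mean * mean
    # variance below the fp cancellation noise floor is exactly zero, so
    # constant images respond 0 rather than sqrt(eps)
    var[var < 1e-12 * (1.0 + np.abs(mean_sq))] = 0.0
    return np.sqrt(np.clip(var, 0.0, None))


def gradient_magnitude(img: np.ndarray, sigma: float) -> np.ndarray:
    gr = _gaussian(img, sigma, order=(1, 0))
    gc = _gaussian(img, sigma, order=(0, 1))
    return np.hypot(gr, gc)


def hessian_determinant(img: np.ndarray, sigma: float) -> np.ndarray:
    irr = _gaussian(img, sigma, order=(2, 0))
    icc = _gaussian(img, sigma, order=(0, 2))
    irc = _gaussian(img, sigma, order=(1, 1))
    return irr * icc - irc * irc


def structure_tensor_coherence(img: np.ndarray, sigma: float) -> np.ndarray:
    """Coherence (l1 - l2) / (l1 + l2 + eps) of the Gaussian-smoothed
    structure tensor, with derivative and integration scale both sigma;
    0 where both eigenvalues vanish."""
    gr = _gaussian(img, sigma, order=(1, 0))
    gc = _gaussian(img, sigma, order=(0, 1))
    jrr = _gaussian(gr * gr, sigma)
    jcc = _gaussian(gc * gc, sigma)
    jrc = _gaussian(gr * gc, sigma)
    disc = np.sqrt((jrr - jcc) ** 2 + 4.0 * jrc * jrc)
    trace = jrr + jcc
    return np.where(trace > COHERENCE_EPS, disc / (trace + COHERENCE_EPS), 0.0)


_FILTERS = {
    "gaussian": gaussian_smooth,
    "laplacian_of_gaussian": laplacian_of_gaussian,
    "weighted_deviation": weighted_deviation,
    "gradient_magnitude": gradient_magnitude,
    "structure_tensor_coherence": structure_tensor_coherence,
    "hessian_determinant": hessian_determinant,
}


def compute_feature_stack(
    image_channels: dict[str, np.ndarray], config: FeatureConfig
) -> FeatureStack:
    """Compute the configured feature bank over named channel rasters.

    ``image_channels`` maps channel names to 2-D float rasters at the
    config's working resolution; every channel the config names must be
    present. Raises on non-finite input.
    """
    missing = [c for c in config.channels if c not in image_channels]
    if missing:
        raise KeyError(f"channels missing from input: {missing}")
    shape = next(iter(image_channels.values())).shape
    data = np.empty(shape + (config.n_columns,), dtype=np.float64)
    col = 0
    for c in config.channels:
        img = np.asarray(image_channels[c], dtype=np.float64)
        if not np.all(np.isfinite(img)):
            raise ValueError(f"channel {c!r} contains non-finite pixels")
        for f in config.features:
            fn = _FILTERS[f]
            for s in config.scales:
                data[:, :, col] = fn(img, s)
                col += 1
    return FeatureStack(
        data=data,
        columns=config.column_metadata(),
        working_resolution_um=config.working_resolution_um,
    )
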