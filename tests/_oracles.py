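"""Independent brute-force oracles for the multiscale filter bank.

Everything here is computed by explicit kernel construction and direct dense
convolution with reflect padding — no scipy.ndimage — so it can serve as an
independent reference for the package's separable implementations.
"""

import numpy as np


def gaussian_kernel_1d(sigma: float, order: int = 0, truncate: float = 4.0):
    """Sampled Gaussian (normalised to unit sum) and its analytic derivatives."""
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
        # DC correction on the centre tap: zero total weight, so constants
        # respond exactly 0
        k[r] -= k.sum()
        return k
    raise ValueError(order)


def dense_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct dense 2-D convolution with reflect (symmetric) padding."""
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    padded = np.pad(img, ((rh, rh), (rw, rw)), mode="symmetric")
    out = np.zeros_like(img, dtype=np.float64)
    h, w = img.shape
    for a in range(kh):
        for b in range(kw):
            # convolution: out[i,j] += K[a,b] * I[i - (a - rh), j - (b - rw)]
            out += kernel[a, b] * padded[rh - (a - rh) : rh - (a - rh) + h,
                                         rw - (b - rw) : rw - (b - rw) + w]
    return out


def kernel_2d(sigma: float, order=(0, 0)) -> np.ndarray:
    return np.outer(
        gaussian_kernel_1d(sigma, order[0]), gaussian_kernel_1d(sigma, order[1])
    )


def oracle_gaussian(img, sigma):
    return dense_convolve(img, kernel_2d(sigma))


def oracle_log(img, sigma):
    k = kernel_2d(sigma, (2, 0)) + kernel_2d(sigma, (0, 2))
    return dense_convolve(img, k)


def oracle_weighted_deviation(img, sigma):
    m = oracle_gaussian(img, sigma)
    msq = oracle_gaussian(img * img, sigma)
    return np.sqrt(np.clip(msq - m * m, 0.0, None))


def oracle_gradient_magnitude(img, sigma):
    gr = dense_convolve(img, kernel_2d(sigma, (1, 0)))
    gc = dense_convolve(img, kernel_2d(sigma, (0, 1)))
    return np.hypot(gr, gc)


def oracle_hessian_determinant(img, sigma):
    irr = dense_convolve(img, kernel_2d(sigma, (2, 0)))
    icc = dense_convolve(img, kernel_2d(sigma, (0, 2)))
    irc = dense_convolve(img, kernel_2d(sigma, (1, 1)))
    return irr * icc - irc * irc


def oracle_coherence(img, sigma, eps=1e-12):
    """Per-pixel eigendecomposition of the smoothed structure tensor."""
    gr = dense_convolve(img, kernel_2d(sigma, (1, 0)))
    gc = dense_convolve(img, kernel_2d(sigma, (0, 1)))
    jrr = oracle_gaussian(gr * gr, sigma)
    jcc = oracle_gaussian(gc * gc, sigma)
    jrc = oracle_gaussian(gr * gc, sigma)
    out = np.zeros_like(img, dtype=np.float64)
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            tensor = np.array([[jrr[i, j], jrc[i, j]], [jrc[i, j], jcc[i, j]]])
            l2, l1 = np.linalg.eigvalsh(tensor)  # ascending
            if l1 + l2 > eps:
                out[i, j] = (l1 - l2) / (l1 + l2 + eps)
    return out


ORACLES = {
    "gaussian": oracle_gaussian,
    "laplacian_of_gaussian": oracle_log,
    "weighted_deviation": oracle_weighted_deviation,
    "gradient_magnitude": oracle_gradient_magnitude,
    "structure_tensor_coherence": oracle_coherence,
    "hessian_determinant": oracle_hessian_determinant,
}
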