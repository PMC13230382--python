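"""Image-quality metrics against a full-view reference: SSIM, PSNR, and
mean +/- 95% CI aggregation.

SSIM follows the Gaussian-windowed formulation (11x11 window, sigma 1.5,
K1=0.01, K2=0.03) with weighted population moments per window; the map is
averaged over the interior after cropping the half-window border. PSNR is
``10 log10(data_range^2 / MSE)``. Both are computed on windowed-normalized
images with ``data_range=1`` in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = ["MetricResult", "ssim", "psnr", "mean_ci"]

_SSIM_WIN = 11
_SSIM_SIGMA = 1.5
_K1 = 0.01
_K2 = 0.03


@dataclass
class MetricResult:
    """Per-image metric values with their mean and a 95% CI."""

    metric: str  # "SSIM" | "PSNR"
    per_image_values: list
    mean: float
    ci95: tuple

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.mean <= hi):
            raise ValueError("CI must bracket the mean")


def _gaussian_kernel(win: int = _SSIM_WIN, sigma: float = _SSIM_SIGMA) -> np.ndarray:
    r = (win - 1) // 2
    ax = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(img: np.ndarray, ref: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity between ``img`` and ``ref``.

    Symmetric in its arguments and equal to 1 iff the images coincide on
    the evaluated interior.
    """
    img = np.asarray(img, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if img.shape != ref.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {ref.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    if min(img.shape) < _SSIM_WIN:
        raise ValueError(f"images must be at least {_SSIM_WIN} pixels per side")
    kernel = _gaussian_kernel()
    pad = (_SSIM_WIN - 1) // 2

    def filt(a):
        return ndimage.correlate(a, kernel, mode="constant")

    mu_x = filt(img)
    mu_y = filt(ref)
    sxx = filt(img * img) - mu_x * mu_x
    syy = filt(ref * ref) - mu_y * mu_y
    sxy = filt(img * ref) - mu_x * mu_y
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * sxy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2)
    s = num / den
    interior = s[pad:-pad, pad:-pad]
    return float(interior.mean())


def psnr(img: np.ndarray, ref: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the images coincide."""
    img = np.asarray(img, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if img.shape != ref.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {ref.shape}")
    mse = float(np.mean((img - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def mean_ci(
    values,
    level: float = 0.95,
    method: str = "t",
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Mean with a two-sided confidence interval.

    ``method='t'`` (default, deterministic) uses the Student-t interval;
    ``method='bootstrap'`` uses a seeded percentile bootstrap.
    Returns ``(mean, low, high)``.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1:
        x = x.ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least two values for a confidence interval")
    m = float(x.mean())
    if method == "t":
        sem = float(x.std(ddof=1)) / np.sqrt(n)
        tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=n - 1))
        half = tcrit * sem
        return m, m - half, m + half
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = x[idx].mean(axis=1)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        return m, min(float(lo), m), max(float(hi), m)
    raise ValueError(f"unknown CI method {method!r}")
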