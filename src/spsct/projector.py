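"""Parallel-beam forward projection (Radon transform) with an exact adjoint.

The projector samples each ray at half-pixel steps and gathers image
values by bilinear interpolation; the backprojector scatters with the
same weights, so the pair (A, Aᵀ) is a matched transpose to floating-point
precision. This matters for the algebraic reconstructions (SIRT/OS-SART),
whose convergence analysis assumes the backprojector is the true adjoint
of the forward operator.

Geometry conventions: angles uniform on [0, π) (parallel-beam period),
detector of ``n_bins`` unit-pitch bins centred on the image centre
``(N-1)/2``. A full acquisition uses 2048 views; sparse-view protocols
keep every k-th view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import save_array

__all__ = [
    "Sinogram",
    "forward_project",
    "back_project",
    "project_at_angles",
    "backproject_at_angles",
    "hu_to_mu",
    "mu_to_hu",
    "subsample_sinogram",
    "save_sinogram",
    "MU_WATER",
]

#: Linear attenuation of water per pixel unit; anchors the HU <-> mu map.
MU_WATER = 0.0192

_RAY_STEP = 0.5  # ray sampling step, pixels
_ANGLE_CHUNK = 32  # angles processed per vectorized block


@dataclass
class Sinogram:
    """Stack of 1-D parallel projections, one row per view angle."""

    data: np.ndarray  # (n_views, n_bins)
    angles_rad: np.ndarray
    detector_spacing: float = 1.0
    n_full_views: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.angles_rad = np.asarray(self.angles_rad, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2-D (n_views, n_bins)")
        if self.angles_rad.shape != (self.data.shape[0],):
            raise ValueError("one angle per sinogram row required")
        if self.angles_rad.size > 1 and np.any(np.diff(self.angles_rad) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles_rad.size and (
            self.angles_rad[0] < 0 or self.angles_rad[-1] >= np.pi
        ):
            raise ValueError("angles must lie in [0, pi)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram data must be finite")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]


def hu_to_mu(hu_image: np.ndarray) -> np.ndarray:
    """Affine map HU -> linear attenuation: mu = mu_water * (1 + HU/1000).

    Water (0 HU) maps to ``MU_WATER`` and air (-1000 HU) to zero.
    """
    hu_image = np.asarray(hu_image, dtype=np.float64)
    if not np.all(np.isfinite(hu_image)):
        raise ValueError("HU image must be finite")
    return MU_WATER * (1.0 + hu_image / 1000.0)


def mu_to_hu(mu_image: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hu_to_mu`."""
    return 1000.0 * (np.asarray(mu_image, dtype=np.float64) / MU_WATER - 1.0)


def _ray_grid(size: int, n_bins: int, spacing: float):
    """Detector offsets s, ray-parameter samples t, and the image centre."""
    half_diag = size * np.sqrt(2.0) / 2.0 + 1.0
    n_t = int(np.ceil(2.0 * half_diag / _RAY_STEP)) + 1
    t = (np.arange(n_t) - (n_t - 1) / 2.0) * _RAY_STEP
    s = (np.arange(n_bins) - (n_bins - 1) / 2.0) * spacing
    return s, t, (size - 1) / 2.0


def _bilinear(x, y, size):
    """Corner indices and weights for bilinear sampling; out-of-grid
    corners get zero weight (rays simply leave the image support)."""
    ix0 = np.floor(x).astype(np.int64)
    iy0 = np.floor(y).astype(np.int64)
    fx = x - ix0
    fy = y - iy0
    out = []
    for dy in (0, 1):
        for dx in (0, 1):
            ix = ix0 + dx
            iy = iy0 + dy
            w = (fx if dx else 1.0 - fx) * (fy if dy else 1.0 - fy)
            valid = (ix >= 0) & (ix < size) & (iy >= 0) & (iy < size)
            idx = np.where(valid, iy * size + ix, 0)
            out.append((idx, np.where(valid, w, 0.0)))
    return out


def _project_numpy(image, angles_rad, n_bins, spacing):
    size = image.shape[0]
    flat = image.ravel()
    s, t, c = _ray_grid(size, n_bins, spacing)
    out = np.empty((angles_rad.size, n_bins), dtype=np.float64)
    for lo in range(0, angles_rad.size, _ANGLE_CHUNK):
        ang = angles_rad[lo : lo + _ANGLE_CHUNK]
        cos = np.cos(ang)[:, None, None]
        sin = np.sin(ang)[:, None, None]
        sv = s[None, :, None]
        tv = t[None, None, :]
        x = c + sv * cos - tv * sin
        y = c + sv * sin + tv * cos
        acc = np.zeros(x.shape, dtype=np.float64)
        for idx, w in _bilinear(x, y, size):
            acc += w * flat[idx]
        out[lo : lo + ang.size] = _RAY_STEP * acc.sum(axis=-1)
    return out


def _backproject_numpy(data, angles_rad, size, spacing):
    n_bins = data.shape[1]
    s, t, c = _ray_grid(size, n_bins, spacing)
    image = np.zeros(size * size, dtype=np.float64)
    for lo in range(0, angles_rad.size, _ANGLE_CHUNK):
        ang = angles_rad[lo : lo + _ANGLE_CHUNK]
        cos = np.cos(ang)[:, None, None]
        sin = np.sin(ang)[:, None, None]
        sv = s[None, :, None]
        tv = t[None, None, :]
        x = c + sv * cos - tv * sin
        y = c + sv * sin + tv * cos
        vals = _RAY_STEP * data[lo : lo + ang.size][:, :, None]
        vals = np.broadcast_to(vals, x.shape)
        for idx, w in _bilinear(x, y, size):
            image += np.bincount(
                idx.ravel(), weights=(w * vals).ravel(), minlength=size * size
            )
    return image.reshape(size, size)


# Hot loops are compiled with numba when available (identical arithmetic,
# ~30x faster); the vectorized NumPy path above remains as fallback and as
# an in-repo cross-check of the kernels.
try:  # pragma: no cover - exercised indirectly
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _project_kernel(image, cos_a, sin_a, s_arr, t_arr, step, c, out):
        size = image.shape[0]
        for a in range(cos_a.size):
            co = cos_a[a]
            si = sin_a[a]
            for ib in range(s_arr.size):
                s = s_arr[ib]
                acc = 0.0
                for it in range(t_arr.size):
                    t = t_arr[it]
                    x = c + s * co - t * si
                    y = c + s * si + t * co
                    ix0 = int(np.floor(x))
                    iy0 = int(np.floor(y))
                    fx = x - ix0
                    fy = y - iy0
                    if 0 <= iy0 < size:
                        if 0 <= ix0 < size:
                            acc += (1.0 - fx) * (1.0 - fy) * image[iy0, ix0]
                        if 0 <= ix0 + 1 < size:
                            acc += fx * (1.0 - fy) * image[iy0, ix0 + 1]
                    if 0 <= iy0 + 1 < size:
                        if 0 <= ix0 < size:
                            acc += (1.0 - fx) * fy * image[iy0 + 1, ix0]
                        if 0 <= ix0 + 1 < size:
                            acc += fx * fy * image[iy0 + 1, ix0 + 1]
                out[a, ib] = step * acc

    @_njit(cache=True, fastmath=False)
    def _backproject_kernel(data, cos_a, sin_a, s_arr, t_arr, step, c, image):
        size = image.shape[0]
        for a in range(cos_a.size):
            co = cos_a[a]
            si = sin_a[a]
            for ib in range(s_arr.size):
                s = s_arr[ib]
                val = step * data[a, ib]
                for it in range(t_arr.size):
                    t = t_arr[it]
                    x = c + s * co - t * si
                    y = c + s * si + t * co
                    ix0 = int(np.floor(x))
                    iy0 = int(np.floor(y))
                    fx = x - ix0
                    fy = y - iy0
                    if 0 <= iy0 < size:
                        if 0 <= ix0 < size:
                            image[iy0, ix0] += (1.0 - fx) * (1.0 - fy) * val
                        if 0 <= ix0 + 1 < size:
                            image[iy0, ix0 + 1] += fx * (1.0 - fy) * val
                    if 0 <= iy0 + 1 < size:
                        if 0 <= ix0 < size:
                            image[iy0 + 1, ix0] += (1.0 - fx) * fy * val
                        if 0 <= ix0 + 1 < size:
                            image[iy0 + 1, ix0 + 1] += fx * fy * val

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def project_at_angles(
    image: np.ndarray,
    angles_rad: np.ndarray,
    n_bins: int,
    spacing: float = 1.0,
) -> np.ndarray:
    """Line integrals of ``image`` at arbitrary angles; rows match angles."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    angles_rad = np.asarray(angles_rad, dtype=np.float64)
    if not _HAVE_NUMBA:
        return _project_numpy(image, angles_rad, n_bins, spacing)
    size = image.shape[0]
    s, t, c = _ray_grid(size, n_bins, spacing)
    out = np.empty((angles_rad.size, n_bins), dtype=np.float64)
    _project_kernel(
        np.ascontiguousarray(image),
        np.cos(angles_rad), np.sin(angles_rad), s, t, _RAY_STEP, c, out,
    )
    return out


def backproject_at_angles(
    data: np.ndarray,
    angles_rad: np.ndarray,
    size: int,
    spacing: float = 1.0,
) -> np.ndarray:
    """Exact adjoint of :func:`project_at_angles` (unfiltered backprojection)."""
    data = np.asarray(data, dtype=np.float64)
    angles_rad = np.asarray(angles_rad, dtype=np.float64)
    if not _HAVE_NUMBA:
        return _backproject_numpy(data, angles_rad, size, spacing)
    n_bins = data.shape[1]
    s, t, c = _ray_grid(size, n_bins, spacing)
    image = np.zeros((size, size), dtype=np.float64)
    _backproject_kernel(
        np.ascontiguousarray(data),
        np.cos(angles_rad), np.sin(angles_rad), s, t, _RAY_STEP, c, image,
    )
    return image


def forward_project(
    image: np.ndarray,
    n_views: int,
    n_bins: int | None = None,
    detector_spacing: float = 1.0,
) -> Sinogram:
    """Simulate a parallel-beam acquisition with ``n_views`` uniform angles.

    Parameters
    ----------
    image:
        Square 2-D attenuation grid (use :func:`hu_to_mu` first for HU data).
    n_views:
        Number of projection angles, uniform on [0, pi).
    n_bins:
        Detector bins; defaults to the image side and must not be smaller.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    size = image.shape[0]
    if n_bins is None:
        n_bins = size
    if n_bins < size:
        raise ValueError("n_bins must be >= image side")
    angles = np.arange(n_views) * np.pi / n_views
    data = project_at_angles(image, angles, n_bins, detector_spacing)
    return Sinogram(
        data=data,
        angles_rad=angles,
        detector_spacing=detector_spacing,
        n_full_views=n_views,
    )


def back_project(sino: Sinogram, size: int) -> np.ndarray:
    """Adjoint applied to a :class:`Sinogram` (no filtering)."""
    return backproject_at_angles(
        sino.data, sino.angles_rad, size, sino.detector_spacing
    )


def subsample_sinogram(full: Sinogram, n_target: int) -> Sinogram:
    """Keep every (n_views / n_target)-th view, starting at view 0.

    Emulates a sparse acquisition: same angular coverage, fewer views.
    ``n_target`` must divide the current view count exactly.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if full.n_views % n_target != 0:
        raise ValueError(
            f"n_target={n_target} must divide the view count {full.n_views}"
        )
    stride = full.n_views // n_target
    return Sinogram(
        data=full.data[::stride].copy(),
        angles_rad=full.angles_rad[::stride].copy(),
        detector_spacing=full.detector_spacing,
        n_full_views=full.n_full_views if full.n_full_views else full.n_views,
    )


def save_sinogram(sino: Sinogram, path: str | Path) -> Path:
    return save_array(
        path,
        sino.data,
        sidecar={
            "kind": "sinogram",
            "angles_rad": sino.angles_rad,
            "detector_spacing": sino.detector_spacing,
            "n_full_views": sino.n_full_views,
        },
    )
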