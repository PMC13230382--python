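"""Seeded synthetic chest-slice phantoms for CT pulmonary angiography.

A phantom is a 2-D Hounsfield-unit image mimicking the content of a
contrast-enhanced chest CT slice: an air background, a soft-tissue body
ellipse with a bony rib ring, two low-attenuation lungs, a handful of
contrast-bright vessel cross-sections inside the lungs and — for
PE-positive cases — soft-tissue embolus disks strictly inside vessels
(filling defects). Ground-truth vessel and embolus masks come with the
image so reconstruction and detection stages can be scored exactly.

All randomness flows through one :class:`numpy.random.Generator` per
phantom, so a (seed, parameters) pair reproduces the phantom bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import save_array

__all__ = [
    "TissueHU",
    "Phantom",
    "generate_phantom",
    "generate_cohort",
    "save_phantom",
]

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass(frozen=True)
class TissueHU:
    """Nominal tissue attenuation values in Hounsfield units."""

    air: float = -1000.0
    lung: float = -800.0
    soft_tissue: float = 40.0
    contrast_vessel: float = 300.0
    bone: float = 700.0


@dataclass
class Phantom:
    """A synthetic CTPA slice with ground truth.

    Attributes
    ----------
    hu_image:
        2-D float array of Hounsfield units in ``[-1024, 3071]``.
    embolus_mask, vessel_mask:
        Boolean arrays; every embolus pixel is also a vessel pixel.
    pe_present:
        True iff ``embolus_mask`` has at least one foreground pixel.
    seed:
        The integer that reproduces this phantom.
    pixel_spacing_mm:
        Isotropic pixel pitch, millimetres.
    """

    hu_image: np.ndarray
    embolus_mask: np.ndarray
    vessel_mask: np.ndarray
    pe_present: bool
    seed: int
    pixel_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.hu_image.ndim != 2:
            raise ValueError("hu_image must be 2-D")
        if self.embolus_mask.shape != self.hu_image.shape:
            raise ValueError("embolus_mask shape mismatch")
        if self.vessel_mask.shape != self.hu_image.shape:
            raise ValueError("vessel_mask shape mismatch")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if np.any(self.embolus_mask & ~self.vessel_mask):
            raise ValueError("embolus pixels must lie inside vessels")
        if bool(self.embolus_mask.any()) != bool(self.pe_present):
            raise ValueError("pe_present inconsistent with embolus_mask")
        if self.hu_image.min() < HU_MIN or self.hu_image.max() > HU_MAX:
            raise ValueError("HU values out of range [-1024, 3071]")


def _ellipse(shape: tuple[int, int], center, semi_axes) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(np.float64)
    cy, cx = center
    ay, ax = semi_axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _disk(shape: tuple[int, int], center, radius: float) -> np.ndarray:
    return _ellipse(shape, center, (radius, radius))


def generate_phantom(
    seed: int,
    size: int,
    pe_present: bool,
    tissues: TissueHU = TissueHU(),
    pixel_spacing_mm: float = 1.0,
) -> Phantom:
    """Generate one chest phantom.

    Parameters
    ----------
    seed:
        RNG seed; same seed and parameters give a bit-identical phantom.
    size:
        Image side in pixels; must be >= 32 and divisible by 16 (the
        artifact network pools four times by a factor of two).
    pe_present:
        Whether to draw 1-3 embolus filling defects inside vessels.
    """
    if size % 16 != 0:
        raise ValueError(f"size must be divisible by 16, got {size}")
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")

    rng = np.random.default_rng(seed)
    n = size
    shape = (n, n)
    c = (n - 1) / 2.0

    hu = np.full(shape, tissues.air, dtype=np.float64)

    # Body ellipse with a thin bony rim (rib ring).
    body_ax = (0.38 * n * rng.uniform(0.95, 1.05), 0.46 * n * rng.uniform(0.95, 1.05))
    body = _ellipse(shape, (c, c), body_ax)
    rim = body & ~_ellipse(shape, (c, c), (0.92 * body_ax[0], 0.92 * body_ax[1]))
    hu[body] = tissues.soft_tissue
    hu[rim] = tissues.bone

    # Two lungs, mirrored about the midline.
    lung_mask = np.zeros(shape, dtype=bool)
    for sign in (-1.0, 1.0):
        lx = c + sign * 0.21 * n * rng.uniform(0.92, 1.08)
        ly = c + 0.02 * n * rng.uniform(-1.0, 1.0)
        ax_ = (0.26 * n * rng.uniform(0.9, 1.05), 0.15 * n * rng.uniform(0.9, 1.05))
        lung = _ellipse(shape, (ly, lx), ax_) & _ellipse(
            shape, (c, c), (0.85 * body_ax[0], 0.85 * body_ax[1])
        )
        lung_mask |= lung
    hu[lung_mask] = tissues.lung

    # Contrast-filled vessel cross-sections, fully inside lung tissue.
    # Rejection sampling against the distance transform keeps each disk
    # at least one pixel clear of the lung boundary.
    dist_in_lung = ndimage.distance_transform_edt(lung_mask)
    n_vessels = int(rng.integers(3, 9))
    r_lo = max(3, int(round(0.030 * n)))
    r_hi = max(r_lo + 1, int(round(0.060 * n)))
    vessel_mask = np.zeros(shape, dtype=bool)
    vessels: list[tuple[float, float, int]] = []
    attempts = 0
    while len(vessels) < n_vessels and attempts < 5000:
        attempts += 1
        r = int(rng.integers(r_lo, r_hi + 1))
        vy = rng.uniform(0, n - 1)
        vx = rng.uniform(0, n - 1)
        iy, ix = int(round(vy)), int(round(vx))
        if not (0 <= iy < n and 0 <= ix < n):
            continue
        if dist_in_lung[iy, ix] <= r + 1:
            continue
        disk = _disk(shape, (vy, vx), r)
        vessel_mask |= disk
        hu[disk] = tissues.contrast_vessel
        vessels.append((vy, vx, r))

    # Embolus = soft-tissue disk strictly inside a vessel (partial filling
    # defect), radius 2..6 px.
    embolus_mask = np.zeros(shape, dtype=bool)
    if pe_present:
        hosts = [v for v in vessels if v[2] >= 3]
        if not hosts:  # degenerate draw; force one adequate vessel
            vy, vx = c, c + 0.21 * n
            r = max(4, r_lo)
            disk = _disk(shape, (vy, vx), r)
            vessel_mask |= disk
            hu[disk] = tissues.contrast_vessel
            hosts = [(vy, vx, r)]
        k = int(rng.integers(1, min(3, len(hosts)) + 1))
        order = rng.permutation(len(hosts))[:k]
        for idx in order:
            vy, vx, r = hosts[idx]
            re = int(min(6, max(2, rng.integers(2, r))))
            re = min(re, r - 1)
            max_off = max(0.0, r - re - 1)
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0, max_off)
            ey, ex = vy + off * np.sin(ang), vx + off * np.cos(ang)
            edisk = _disk(shape, (ey, ex), re) & vessel_mask
            embolus_mask |= edisk
            hu[edisk] = tissues.soft_tissue
        if not embolus_mask.any():  # numerically impossible, but be safe
            vy, vx, r = hosts[0]
            edisk = _disk(shape, (vy, vx), 2) & vessel_mask
            embolus_mask |= edisk
            hu[edisk] = tissues.soft_tissue

    np.clip(hu, HU_MIN, HU_MAX, out=hu)
    return Phantom(
        hu_image=hu,
        embolus_mask=embolus_mask,
        vessel_mask=vessel_mask,
        pe_present=bool(pe_present),
        seed=int(seed),
        pixel_spacing_mm=pixel_spacing_mm,
    )


def generate_cohort(
    n: int,
    prevalence: float,
    seed: int,
    size: int = 512,
    tissues: TissueHU = TissueHU(),
) -> list[Phantom]:
    """Generate ``n`` phantoms with exactly ``round(n * prevalence)``
    PE-positive cases, in a seeded random order.

    Per-phantom seeds are drawn without replacement from the cohort RNG,
    so members are independent and the cohort is reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * prevalence))
    labels = np.zeros(n, dtype=bool)
    labels[:n_pos] = True
    rng.shuffle(labels)
    seeds: set[int] = set()
    while len(seeds) < n:
        seeds.add(int(rng.integers(0, 2**31)))
    seed_list = sorted(seeds)
    rng.shuffle(seed_list)
    return [
        generate_phantom(seed_list[i], size, bool(labels[i]), tissues=tissues)
        for i in range(n)
    ]


def save_phantom(ph: Phantom, path: str | Path) -> Path:
    """Write image + masks as one stacked array with a JSON sidecar."""
    stack = np.stack(
        [ph.hu_image, ph.embolus_mask.astype(np.float64), ph.vessel_mask.astype(np.float64)]
    )
    return save_array(
        path,
        stack,
        sidecar={
            "kind": "phantom",
            "layers": ["hu_image", "embolus_mask", "vessel_mask"],
            "pe_present": ph.pe_present,
            "seed": ph.seed,
            "pixel_spacing_mm": ph.pixel_spacing_mm,
        },
    )
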