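"""Array-container I/O: ``.npy`` payload plus a JSON sidecar of metadata.

Every artifact the toolkit writes (phantoms, sinograms, reconstructions,
model checkpoints) is a plain NumPy array file accompanied by
``<stem>.json`` holding provenance: seeds, geometry, algorithm parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["save_array", "load_array", "read_dicom_slice", "export_png"]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_array(path: str | Path, array: np.ndarray, sidecar: dict | None = None) -> Path:
    """Write ``array`` to ``<path>.npy`` and ``sidecar`` to ``<path>.json``.

    Returns the ``.npy`` path. ``path`` may or may not carry the suffix.
    """
    path = Path(path)
    if path.suffix == ".npy":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)
    npy = path.with_suffix(".npy")
    np.save(npy, array)
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(_jsonable(sidecar), indent=2))
    return npy


def load_array(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load ``<path>.npy`` and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    if path.suffix == ".npy":
        path = path.with_suffix("")
    arr = np.load(path.with_suffix(".npy"))
    side = path.with_suffix(".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return arr, meta


def export_png(windowed: np.ndarray, path: str | Path) -> Path:
    """Write a windowed [0, 1] image as 16-bit grayscale PNG.

    Optional display/export helper; requires :mod:`imageio`.
    """
    try:
        import imageio.v3 as iio
    except ImportError as exc:  # pragma: no cover
        raise ImportError("PNG export requires imageio") from exc
    arr = np.clip(np.asarray(windowed, dtype=np.float64), 0.0, 1.0)
    path = Path(path).with_suffix(".png")
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.round(arr * 65535.0).astype(np.uint16))
    return path


def read_dicom_slice(path: str | Path) -> np.ndarray:
    """Read a single DICOM slice and return it in Hounsfield units.

    Optional convenience for feeding real CT slices through the pipeline;
    requires :mod:`pydicom`.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading DICOM slices requires pydicom") from exc
    ds = pydicom.dcmread(str(path))
    img = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return img * slope + intercept
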