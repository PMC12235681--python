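"""Raw OCT intensity handling: greyscale conversion and scan calibration.

Spectral-domain OCT devices export raw A-scan intensities whose dynamic
range is far too wide for direct display. The classical visualization
compresses the range with a fourth root and bins the result into 256
grey levels; that greyscale image is what graders annotate. This module
implements that conversion and carries the per-scan pixel calibration
(lateral pixel width and axial pixel depth, in micrometres) needed to
convert pixel morphometrics to metric units.

Coordinate convention: 0-based ``(row, col)``; row 0 is the innermost
retina (top of image) and rows increase with depth; columns increase in
the lateral scan direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "ScanCalibration",
    "fourth_root_rescale",
    "pixel_area",
    "load_raw",
    "save_grey",
    "load_grey",
    "load_calibration",
    "save_calibration",
]


@dataclass(frozen=True)
class ScanCalibration:
    """Physical pixel dimensions of one B-scan.

    Parameters
    ----------
    pixel_width_um : float
        Lateral extent of one pixel (μm per column). Device-reported;
        varies between scans with eye geometry and scan focus.
    pixel_depth_um : float
        Axial extent of one pixel (μm per row). Device constant for a
        given scan protocol (3.87 μm for the 496-row protocol modelled
        by the synthetic generator).
    """

    pixel_width_um: float
    pixel_depth_um: float

    def __post_init__(self) -> None:
        if not (self.pixel_width_um > 0 and np.isfinite(self.pixel_width_um)):
            raise ValueError(
                f"pixel_width_um must be positive, got {self.pixel_width_um}")
        if not (self.pixel_depth_um > 0 and np.isfinite(self.pixel_depth_um)):
            raise ValueError(
                f"pixel_depth_um must be positive, got {self.pixel_depth_um}")


def pixel_area(calib: ScanCalibration) -> float:
    """Area of one pixel in μm² (pixel width × pixel depth)."""
    return calib.pixel_width_um * calib.pixel_depth_um


def fourth_root_rescale(raw: np.ndarray,
                        reference_max: Optional[float] = None) -> np.ndarray:
    """Convert raw OCT intensities to an 8-bit greyscale image.

    Each intensity ``v`` is mapped to ``round(255 * (v / m)**0.25)``
    with round-half-up, where ``m`` is ``reference_max`` (a fixed device
    range) or, by default, the per-scan maximum. The map is monotone, so
    grading decisions based on relative brightness are preserved.

    Parameters
    ----------
    raw : ndarray
        2-D array of non-negative, finite intensities (rows = depth).
    reference_max : float, optional
        Normalization ceiling; must be at least ``raw.max()``. Default:
        per-scan maximum. An all-zero scan yields an all-zero image.

    Returns
    -------
    ndarray of uint8, same shape as ``raw``.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("raw scan must be a non-empty 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("raw intensities must be finite")
    if np.any(arr < 0):
        raise ValueError("raw intensities must be non-negative")
    peak = float(arr.max())
    if reference_max is None:
        reference_max = peak
    elif reference_max < peak:
        raise ValueError(
            f"reference_max {reference_max} is below the scan maximum {peak}")
    if reference_max == 0.0:  # all-zero scan with per-scan max
        return np.zeros_like(arr, dtype=np.uint8)
    scaled = 255.0 * (arr / reference_max) ** 0.25
    # round half up (np.round rounds half to even)
    return np.floor(scaled + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# File I/O: raw arrays from NPY/TIFF, grey images as PNG/TIFF, calibration
# sidecars as YAML or JSON.
# ---------------------------------------------------------------------------

def load_raw(path: Union[str, Path]) -> np.ndarray:
    """Load a raw intensity array from an ``.npy`` or 16-bit/float TIFF."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, "
                         f"got shape {arr.shape}")
    return arr


def save_grey(grey: np.ndarray, path: Union[str, Path]) -> None:
    """Write an 8-bit greyscale image (PNG or TIFF by extension)."""
    import imageio.v3 as iio

    grey = np.asarray(grey)
    if grey.dtype != np.uint8:
        raise ValueError("grey image must be uint8")
    iio.imwrite(Path(path), grey)


def load_grey(path: Union[str, Path]) -> np.ndarray:
    """Read an 8-bit greyscale image; RGB input is rejected."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected greyscale, got shape {arr.shape}")
    return arr.astype(np.uint8)


def load_calibration(path: Union[str, Path]) -> ScanCalibration:
    """Read a ``{pixel_width_um, pixel_depth_um}`` sidecar (YAML or JSON)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return ScanCalibration(pixel_width_um=float(data["pixel_width_um"]),
                           pixel_depth_um=float(data["pixel_depth_um"]))


def save_calibration(calib: ScanCalibration, path: Union[str, Path]) -> None:
    path = Path(path)
    data = {"pixel_width_um": calib.pixel_width_um,
            "pixel_depth_um": calib.pixel_depth_um}
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(data), encoding="utf-8")
    else:
        path.write_text(json.dumps(data, indent=1), encoding="utf-8")
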