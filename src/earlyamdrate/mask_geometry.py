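"""Lesion mask extraction, validation and morphometry.

Graders annotate a lesion by painting its pixels in colour on top of
the greyscale B-scan; distinct lesions on the same scan get distinct
colours. A pixel belongs to a mask iff its RGB channels are not all
equal (colour instead of a grey tone), and masks are grouped by exact
colour. A valid mask is a single 8-connected region of at least two
pixels.

From a mask and the scan calibration the instrument derives metric
morphometrics: the cutting area (pixel count × pixel area), the
projected diameter (lateral column span × pixel width — the lateral
axis because fundus-based diameter conventions project onto the
transverse plane and because lateral and axial pixel scales differ),
and the real-valued centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .oct_preprocess import ScanCalibration, pixel_area
from .schema import Violation

__all__ = [
    "LesionMask",
    "LesionGeometry",
    "MaskExtractionError",
    "validate_mask",
    "extract_masks",
    "measure_geometry",
    "render_masks",
    "geometry_table",
    "masks_to_rle",
    "masks_from_rle",
    "save_label_map",
]

Colour = tuple[int, int, int]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass(frozen=True)
class LesionMask:
    """One lesion's pixel set on one scan, identified by its colour."""

    pixel_set: frozenset
    colour_id: Colour
    scan_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixel_set", frozenset(
            (int(r), int(c)) for r, c in self.pixel_set))
        colour = tuple(int(v) for v in self.colour_id)
        if len(colour) != 3 or not all(0 <= v <= 255 for v in colour):
            raise ValueError(f"colour_id must be an RGB triple, got {colour}")
        if colour[0] == colour[1] == colour[2]:
            raise ValueError(
                f"colour_id {colour} is a grey tone and cannot mark a lesion")
        object.__setattr__(self, "colour_id", colour)

    def translate(self, d_row: int, d_col: int) -> "LesionMask":
        return LesionMask(
            frozenset((r + d_row, c + d_col) for r, c in self.pixel_set),
            self.colour_id, self.scan_id)

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), inclusive."""
        rows = [r for r, _ in self.pixel_set]
        cols = [c for _, c in self.pixel_set]
        return min(rows), min(cols), max(rows), max(cols)


@dataclass(frozen=True)
class LesionGeometry:
    """Morphometrics of one lesion mask, in pixels and metric units."""

    area_px: int
    area_um2: float
    diameter_px: int
    diameter_um: float
    centroid: tuple[float, float]  # (row, col)


class MaskExtractionError(ValueError):
    """An annotated colour violates the masking rules."""

    def __init__(self, message: str, colour: Optional[Colour] = None):
        self.colour = colour
        super().__init__(message)


def _is_connected(pixels: frozenset) -> bool:
    rows = np.array([r for r, _ in pixels])
    cols = np.array([c for _, c in pixels])
    grid = np.zeros((rows.max() - rows.min() + 1,
                     cols.max() - cols.min() + 1), dtype=bool)
    grid[rows - rows.min(), cols - cols.min()] = True
    _, n_components = ndimage.label(grid, structure=_EIGHT)
    return n_components == 1


def validate_mask(mask: LesionMask) -> list[Violation]:
    """Check the masking rules: ≥2 pixels, one 8-connected region.

    Violations are returned as data so all annotation problems on a
    scan can be reported together.
    """
    if not mask.pixel_set:
        raise ValueError("mask has an empty pixel set")
    violations: list[Violation] = []
    if len(mask.pixel_set) < 2:
        violations.append(Violation(
            ("MASK",),
            f"mask {mask.colour_id} has {len(mask.pixel_set)} pixel(s); "
            "the minimal size is 2",
        ))
    if len(mask.pixel_set) >= 2 and not _is_connected(mask.pixel_set):
        violations.append(Violation(
            ("MASK",),
            f"mask {mask.colour_id} is not a connected area "
            "(horizontal, vertical or diagonal connections required)",
        ))
    return violations


def extract_masks(overlay: np.ndarray,
                  base: Optional[np.ndarray] = None,
                  scan_id: str = "",
                  channel_tolerance: int = 0) -> list[LesionMask]:
    """Recover lesion masks from a colour-annotated B-scan overlay.

    A pixel is annotated iff its channel spread exceeds
    ``channel_tolerance`` (default 0: any pixel that is not an exact
    grey tone). Annotated pixels are grouped by exact colour — no
    nearest-colour clustering, so touching lesions in different colours
    stay separate. Every group must satisfy :func:`validate_mask`.

    Masks are returned sorted by (min column, min row, colour bytes)
    for deterministic downstream numbering.

    Raises
    ------
    MaskExtractionError
        If any colour forms an invalid mask (too small or disconnected).
    ValueError
        If ``overlay`` is not an RGB image, or its shape (or unannotated
        pixels, when ``base`` is given) disagrees with ``base``.
    """
    overlay = np.asarray(overlay)
    if overlay.ndim != 3 or overlay.shape[2] < 3:
        raise ValueError(f"overlay must be H×W×3 RGB, got shape {overlay.shape}")
    rgb = overlay[..., :3].astype(np.int16)
    if base is not None:
        base = np.asarray(base)
        if base.shape != rgb.shape[:2]:
            raise ValueError(
                f"overlay shape {rgb.shape[:2]} does not match base shape "
                f"{base.shape}")
    spread = rgb.max(axis=2) - rgb.min(axis=2)
    annotated = spread > channel_tolerance

    if base is not None:
        grey_pixels = rgb[~annotated]
        base_pixels = base[~annotated].astype(np.int16)
        if grey_pixels.size and np.any(
                np.abs(grey_pixels - base_pixels[:, None]) > channel_tolerance):
            raise ValueError(
                "unannotated overlay pixels differ from the base image")

    masks: list[LesionMask] = []
    problems: list[str] = []
    coords = np.argwhere(annotated)
    if coords.size:
        colours = rgb[annotated]
        unique_colours, inverse = np.unique(colours, axis=0, return_inverse=True)
        for k, colour in enumerate(unique_colours):
            pts = coords[inverse == k]
            pixel_set = frozenset((int(r), int(c)) for r, c in pts)
            mask = LesionMask(pixel_set, tuple(int(v) for v in colour), scan_id)
            violations = validate_mask(mask)
            if violations:
                problems.extend(str(v) for v in violations)
            else:
                masks.append(mask)
    if problems:
        raise MaskExtractionError("; ".join(problems))
    masks.sort(key=lambda m: (min(c for _, c in m.pixel_set),
                              min(r for r, _ in m.pixel_set),
                              m.colour_id))
    return masks


def measure_geometry(mask: LesionMask, calib: ScanCalibration) -> LesionGeometry:
    """Derive cutting area, projected diameter and centroid from a mask.

    ``diameter_px`` is the inclusive column span ``max(col) − min(col) + 1``;
    metric values use the calibration exactly
    (``area_um2 = area_px × pixel_width × pixel_depth``).
    """
    violations = validate_mask(mask)
    if violations:
        raise ValueError("invalid mask: " + "; ".join(str(v) for v in violations))
    pts = np.array(sorted(mask.pixel_set), dtype=float)
    area_px = len(mask.pixel_set)
    cols = pts[:, 1]
    diameter_px = int(cols.max() - cols.min()) + 1
    centroid = (float(pts[:, 0].mean()), float(cols.mean()))
    return LesionGeometry(
        area_px=area_px,
        area_um2=area_px * pixel_area(calib),
        diameter_px=diameter_px,
        diameter_um=diameter_px * calib.pixel_width_um,
        centroid=centroid,
    )


def render_masks(base: np.ndarray, masks: Iterable[LesionMask]) -> np.ndarray:
    """Paint masks (hard-edged, no anti-aliasing) over a greyscale B-scan.

    Inverse of :func:`extract_masks` on valid annotations. Masks must be
    pairwise disjoint and use pairwise distinct colours.
    """
    base = np.asarray(base)
    if base.ndim != 2:
        raise ValueError(f"base must be a 2-D greyscale image, got {base.shape}")
    overlay = np.repeat(base.astype(np.uint8)[:, :, None], 3, axis=2).copy()
    painted: set = set()
    seen_colours: set[Colour] = set()
    for mask in masks:
        if mask.colour_id in seen_colours:
            raise ValueError(f"colour {mask.colour_id} used by two masks")
        seen_colours.add(mask.colour_id)
        if painted & mask.pixel_set:
            raise ValueError(
                f"mask {mask.colour_id} overlaps a previously drawn mask")
        painted |= mask.pixel_set
        for r, c in mask.pixel_set:
            if not (0 <= r < base.shape[0] and 0 <= c < base.shape[1]):
                raise ValueError(
                    f"mask {mask.colour_id} pixel ({r}, {c}) outside the image")
            overlay[r, c] = mask.colour_id
    return overlay


def geometry_table(masks: Sequence[LesionMask],
                   calib: ScanCalibration,
                   lesion_ids: Optional[Sequence[str]] = None):
    """Geometry of several masks as a DataFrame (export layout).

    Columns: scan_id, lesion_id, colour, area_px, area_um2, diameter_px,
    diameter_um, centroid_row, centroid_col. Centroids are reported to
    two decimals.
    """
    import pandas as pd

    if lesion_ids is None:
        lesion_ids = [str(i + 1) for i in range(len(masks))]
    rows = []
    for lesion_id, mask in zip(lesion_ids, masks):
        geom = measure_geometry(mask, calib)
        rows.append({
            "scan_id": mask.scan_id,
            "lesion_id": lesion_id,
            "colour": "#%02x%02x%02x" % mask.colour_id,
            "area_px": geom.area_px,
            "area_um2": geom.area_um2,
            "diameter_px": geom.diameter_px,
            "diameter_um": geom.diameter_um,
            "centroid_row": round(geom.centroid[0], 2),
            "centroid_col": round(geom.centroid[1], 2),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mask export: per-lesion run-length encoding (row, col_start, run_length)
# in JSON, plus an indexed label-map PNG.
# ---------------------------------------------------------------------------

def masks_to_rle(masks: Sequence[LesionMask]) -> list[dict]:
    out = []
    for mask in masks:
        runs = []
        by_row: dict[int, list[int]] = {}
        for r, c in mask.pixel_set:
            by_row.setdefault(r, []).append(c)
        for r in sorted(by_row):
            cols = sorted(by_row[r])
            start = prev = cols[0]
            for c in cols[1:]:
                if c == prev + 1:
                    prev = c
                    continue
                runs.append([r, start, prev - start + 1])
                start = prev = c
            runs.append([r, start, prev - start + 1])
        out.append({"scan_id": mask.scan_id,
                    "colour": list(mask.colour_id),
                    "runs": runs})
    return out


def masks_from_rle(data: Iterable[dict]) -> list[LesionMask]:
    masks = []
    for entry in data:
        pixels = set()
        for r, start, length in entry["runs"]:
            pixels.update((r, c) for c in range(start, start + length))
        masks.append(LesionMask(frozenset(pixels),
                                tuple(entry["colour"]),
                                entry.get("scan_id", "")))
    return masks


def save_label_map(masks: Sequence[LesionMask], shape: tuple[int, int],
                   path: Union[str, Path]) -> None:
    """Write masks as an 8-bit label image (0 = background, k = mask k)."""
    import imageio.v3 as iio

    label = np.zeros(shape, dtype=np.uint8)
    for k, mask in enumerate(masks, start=1):
        for r, c in mask.pixel_set:
            label[r, c] = k
    iio.imwrite(Path(path), label)


def save_masks_json(masks: Sequence[LesionMask], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(masks_to_rle(masks), indent=1),
                          encoding="utf-8")


def load_masks_json(path: Union[str, Path]) -> list[LesionMask]:
    return masks_from_rle(json.loads(Path(path).read_text(encoding="utf-8")))
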