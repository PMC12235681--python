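"""Seeded synthetic OCT B-scans with ground-truth masks and gradings.

No public dataset with per-lesion Early-AMD gradings exists, so every
other module is exercised against scans produced here. A synthetic
B-scan is a 496×512 reflectivity field with five outer-retinal bands
(ELM, EZ, IZ, outer RPE complex, BM) in the lower third of the image,
into which lesions are injected:

* **drusen** — a parabolic dome of deposit between BM and the RPE,
  elevating the RPE (and the bands above it) upward;
* **SDD** — a mound of deposit sitting on top of an undisturbed RPE,
  draping the bands above it upward;
* **hyper-reflective focus** — a bright elliptical blob above the
  outer bands, without banded deposit material.

Multiplicative log-normal speckle is applied to the reflectivity
field before fourth-root greyscale conversion — a pragmatic stand-in
for OCT speckle, not a physical model. Lesions are drawn hard-edged,
so exact-colour mask extraction recovers the ground truth bit-for-bit.

Cohort defaults emulate the study conditions the instrument was
demonstrated on: one leading scan per patient, on average 1.98 lesions
per scan with a drusen : SDD : hyper-reflective : ungradable mix of
142 : 54 : 1 : 1, lesion diameters log-normal with median 154.8 μm and
log-scale spread 0.6, and per-scan lateral pixel widths scattered
around 11.27 μm at a fixed 3.87 μm axial pixel depth.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical seeds give bit-identical
datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .mask_geometry import (LesionGeometry, LesionMask, measure_geometry,
                            render_masks)
from .oct_preprocess import ScanCalibration, fourth_root_rescale
from .phenotyping import LesionType, classify_lesion
from .schema import (Brightness, GradingRecord, LayerState, Progression,
                     Separability, validate_record)

__all__ = [
    "RetinaModel",
    "LesionSpec",
    "SyntheticScan",
    "CohortDataset",
    "DEFAULT_DIAMETER_MEANLOG",
    "DEFAULT_DIAMETER_SDLOG",
    "DEFAULT_TYPE_MIX",
    "generate_bscan",
    "generate_cohort",
    "write_cohort",
]

#: median projected diameter 154.8 μm on the log scale
DEFAULT_DIAMETER_MEANLOG = math.log(154.8)
#: log-scale spread of lesion diameters
DEFAULT_DIAMETER_SDLOG = 0.6
#: lesion-type proportions (142 drusen : 54 SDD : 1 focus : 1 ungradable)
DEFAULT_TYPE_MIX: Mapping[LesionType, float] = {
    LesionType.DRUSEN: 142 / 198,
    LesionType.SDD: 54 / 198,
    LesionType.HYPERREFLECTIVE_ONLY: 1 / 198,
    LesionType.UNGRADABLE: 1 / 198,
}

_PALETTE: tuple[tuple[int, int, int], ...] = (
    (255, 0, 0), (0, 160, 0), (0, 80, 255), (255, 200, 0), (200, 0, 200),
    (0, 200, 200), (255, 128, 0), (128, 0, 255), (0, 255, 100), (255, 0, 128),
)

_BRIGHTNESS_REFLECTIVITY: Mapping[Brightness, float] = {
    Brightness.LOW: 0.25,
    Brightness.MODERATE: 0.55,
    Brightness.HIGH: 0.95,
}


@dataclass(frozen=True)
class RetinaModel:
    """Band geometry and reflectivities of the synthetic outer retina.

    ``band_rows`` gives the top row of each band (rows increase with
    depth, so ELM < EZ < IZ < RPE < BM); ``band_thickness`` the band
    height in rows; ``band_reflectivity`` relative reflectivity in
    (0, 1]. Defaults place the bands in the lower third of a 496-row
    scan with the RPE resting directly on BM.
    """

    n_rows: int = 496
    n_cols: int = 512
    band_rows: Mapping[str, int] = field(default_factory=lambda: {
        "ELM": 360, "EZ": 368, "IZ": 376, "RPE": 382, "BM": 389})
    band_thickness: Mapping[str, int] = field(default_factory=lambda: {
        "ELM": 2, "EZ": 4, "IZ": 2, "RPE": 5, "BM": 2})
    band_reflectivity: Mapping[str, float] = field(default_factory=lambda: {
        "ELM": 0.45, "EZ": 0.90, "IZ": 0.50, "RPE": 0.95, "BM": 0.40})
    background_reflectivity: float = 0.05
    speckle_sigma: float = 0.25  # log-sd of multiplicative speckle

    def __post_init__(self) -> None:
        order = ["ELM", "EZ", "IZ", "RPE", "BM"]
        rows = [self.band_rows[b] for b in order]
        if rows != sorted(rows) or len(set(rows)) != 5:
            raise ValueError(
                "band rows must strictly increase with depth "
                f"(ELM < EZ < IZ < RPE < BM), got {self.band_rows}")
        for band in order:
            if not 0 < self.band_reflectivity[band] <= 1:
                raise ValueError(f"reflectivity of {band} must be in (0, 1]")
        for band in order[:-1]:
            nxt = order[order.index(band) + 1]
            if self.band_rows[band] + self.band_thickness[band] > self.band_rows[nxt]:
                raise ValueError(f"band {band} overlaps band {nxt}")


@dataclass(frozen=True)
class LesionSpec:
    """Recipe for one injected lesion.

    ``diameter_um`` is the target projected diameter; the rendered mask
    spans ``max(2, round(diameter_um / pixel_width))`` columns. Dome
    height defaults to ``height_factor`` times the diameter (in μm,
    converted to rows with the axial calibration).
    """

    lesion_type: LesionType
    centre_col: int
    diameter_um: float
    brightness: Brightness = Brightness.MODERATE
    confluent: bool = False
    drusen_ooze: bool = False
    height_factor: float = 0.4
    colour: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError(f"diameter_um must be positive, got {self.diameter_um}")
        if not 0 < self.height_factor <= 1:
            raise ValueError("height_factor must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticScan:
    """One generated B-scan with full ground truth."""

    scan_id: str
    grey: np.ndarray                       # uint8 greyscale image
    overlay: np.ndarray                    # RGB image with masks drawn in
    masks: tuple[LesionMask, ...]          # truth masks, lesion order
    records: tuple[GradingRecord, ...]     # truth gradings, lesion order
    geometries: tuple[LesionGeometry, ...]  # truth morphometrics
    lesion_types: tuple[LesionType, ...]   # injected types
    specs: tuple[LesionSpec, ...]          # the recipes that were rendered
    calibration: ScanCalibration
    seed: int


def _diameter_px(diameter_um: float, calib: ScanCalibration) -> int:
    return max(2, int(round(diameter_um / calib.pixel_width_um)))


def _height_px(spec: LesionSpec, calib: ScanCalibration) -> int:
    return max(2, int(round(spec.height_factor * spec.diameter_um
                            / calib.pixel_depth_um)))


def footprint_px(spec: LesionSpec, calib: ScanCalibration) -> tuple[int, int]:
    """Inclusive column range (first, last) the lesion will occupy."""
    d = _diameter_px(spec.diameter_um, calib)
    first = spec.centre_col - d // 2
    return first, first + d - 1


def _column_heights(d: int, h: int) -> np.ndarray:
    """Parabolic dome profile: per-column deposit height ≥ 1, peak = h."""
    if d == 1:
        return np.array([max(1, h)])
    t = np.linspace(-1.0, 1.0, d)
    return np.maximum(1, np.round(h * (1.0 - t ** 2)).astype(int))


def _lesion_pixels(spec: LesionSpec, model: RetinaModel,
                   calib: ScanCalibration) -> tuple[frozenset, np.ndarray]:
    """Pixel set of the deposit plus per-column band elevation."""
    d = _diameter_px(spec.diameter_um, calib)
    h = _height_px(spec, calib)
    first, last = footprint_px(spec, calib)
    if first < 0 or last >= model.n_cols:
        raise ValueError(
            f"lesion at column {spec.centre_col} (diameter {d} px) exceeds "
            f"the {model.n_cols}-column field")
    heights = _column_heights(d, h)
    elevation = np.zeros(model.n_cols, dtype=int)
    pixels: set[tuple[int, int]] = set()

    rpe_top = model.band_rows["RPE"]
    rpe_bottom = rpe_top + model.band_thickness["RPE"]  # first row below RPE
    bm_top = model.band_rows["BM"]

    if spec.lesion_type is LesionType.HYPERREFLECTIVE_ONLY:
        # bright elliptical blob above the outer bands, no banded deposit
        centre_row = model.band_rows["ELM"] - max(6, h // 2) - 2
        a, b = max(1, d // 2), max(1, h // 2)
        for dc in range(-a, a + 1):
            for dr in range(-b, b + 1):
                if (dc / a) ** 2 + (dr / b) ** 2 <= 1.0:
                    pixels.add((centre_row + dr, spec.centre_col + dc))
    elif spec.lesion_type is LesionType.SDD:
        # mound resting on top of an undisturbed RPE
        for k, col in enumerate(range(first, last + 1)):
            e = int(heights[k])
            elevation[col] = e
            for row in range(rpe_top - e, rpe_top):
                pixels.add((row, col))
    else:
        # drusen (and the ungradable lesion, rendered drusen-like):
        # deposit between BM and the elevated RPE
        gap = bm_top - rpe_bottom  # rows naturally between RPE and BM
        for k, col in enumerate(range(first, last + 1)):
            e = int(heights[k])
            elevation[col] = e
            for row in range(bm_top - gap - e, bm_top):
                pixels.add((row, col))
    return frozenset(pixels), elevation


def _truth_record(spec: LesionSpec, scan_id: str, lesion_id: str) -> GradingRecord:
    layers: dict[str, LayerState]
    if spec.lesion_type is LesionType.DRUSEN:
        layers = dict(elm=LayerState.BENT_UP, ez=LayerState.BENT_UP,
                      iz=LayerState.BENT_UP, rpe=LayerState.BENT_UP,
                      bm=LayerState.UNCHANGED)
    elif spec.lesion_type is LesionType.SDD:
        layers = dict(elm=LayerState.BENT_UP, ez=LayerState.BENT_UP,
                      iz=LayerState.BENT_UP, rpe=LayerState.UNCHANGED,
                      bm=LayerState.UNCHANGED)
    elif spec.lesion_type is LesionType.HYPERREFLECTIVE_ONLY:
        layers = dict(elm=LayerState.BENT_UP, ez=LayerState.BENT_UP,
                      iz=LayerState.BENT_UP, rpe=LayerState.BENT_UP,
                      bm=LayerState.UNCHANGED)
    else:  # UNGRADABLE: deposit visible but RPE state cannot be assessed
        layers = dict(elm=LayerState.BENT_UP, ez=LayerState.BENT_UP,
                      iz=LayerState.NOT_GRADABLE, rpe=LayerState.NOT_GRADABLE,
                      bm=LayerState.NOT_GRADABLE)
    record = GradingRecord(
        scan_id=scan_id,
        lesion_id=lesion_id,
        scan_gradable=True,
        **layers,
        iz_rpe_separable=(Separability.UNASSESSED
                          if spec.lesion_type in (LesionType.UNGRADABLE,
                                                  LesionType.HYPERREFLECTIVE_ONLY)
                          else Separability.YES),
        brightness=(Brightness.HIGH
                    if spec.lesion_type is LesionType.HYPERREFLECTIVE_ONLY
                    else spec.brightness),
        confluent=spec.confluent,
        drusen_ooze=spec.drusen_ooze,
        hyperreflective_only=(
            spec.lesion_type is LesionType.HYPERREFLECTIVE_ONLY),
        progression=Progression.NOT_ASSESSED,
    )
    assert not validate_record(record)
    assert classify_lesion(record) is spec.lesion_type
    return record


def generate_bscan(model: RetinaModel,
                   lesions: Sequence[LesionSpec],
                   calib: ScanCalibration,
                   seed: int,
                   scan_id: str = "scan-000") -> SyntheticScan:
    """Render one synthetic B-scan with exact ground truth.

    Deterministic for a fixed seed. Lesion masks are guaranteed valid
    (8-connected, ≥ 2 pixels) and pairwise disjoint; lesion footprints
    of different colours may touch or overlap only when both lesions
    are marked confluent — overlapping pixels are then assigned to the
    earlier lesion so masks stay disjoint with a visible delineation.
    """
    rng = np.random.default_rng(seed)

    specs = list(lesions)
    pixel_sets: list[frozenset] = []
    elevations = np.zeros(model.n_cols, dtype=int)
    claimed: set[tuple[int, int]] = set()
    for i, spec in enumerate(specs):
        pixels, elevation = _lesion_pixels(spec, model, calib)
        shared = pixels & claimed
        if shared:
            partners = [j for j, prev in enumerate(pixel_sets) if prev & pixels]
            if not (spec.confluent and all(specs[j].confluent for j in partners)):
                raise ValueError(
                    f"lesion {i + 1} overlaps lesion(s) "
                    f"{[j + 1 for j in partners]} but they are not all "
                    "marked confluent")
            pixels = pixels - claimed
            if len(pixels) < 2:
                raise ValueError(
                    f"confluent lesion {i + 1} is fully occluded by its "
                    "neighbours")
        claimed |= pixels
        pixel_sets.append(pixels)
        elevations = np.maximum(elevations, elevation)

    # reflectivity field: background, bands (draped over elevations), deposits
    field_img = np.full((model.n_rows, model.n_cols),
                        model.background_reflectivity, dtype=float)
    sdd_lift = np.zeros(model.n_cols, dtype=int)
    for i, spec in enumerate(specs):
        if spec.lesion_type is LesionType.SDD:
            first, last = footprint_px(spec, calib)
            heights = _column_heights(_diameter_px(spec.diameter_um, calib),
                                      _height_px(spec, calib))
            sdd_lift[first:last + 1] = np.maximum(
                sdd_lift[first:last + 1], heights)
    for band in ("ELM", "EZ", "IZ", "RPE", "BM"):
        top = model.band_rows[band]
        thick = model.band_thickness[band]
        refl = model.band_reflectivity[band]
        if band == "BM":
            shift = np.zeros(model.n_cols, dtype=int)  # BM stays put
        elif band == "RPE":
            shift = elevations - sdd_lift  # RPE unaffected by SDD mounds
        else:
            shift = elevations  # inner bands drape over everything
        for col in range(model.n_cols):
            r0 = top - int(shift[col])
            field_img[max(0, r0):max(0, r0 + thick), col] = refl
    for spec, pixels in zip(specs, pixel_sets):
        refl = _BRIGHTNESS_REFLECTIVITY.get(spec.brightness, 0.55)
        for r, c in pixels:
            field_img[r, c] = refl

    if model.speckle_sigma > 0:
        sigma = model.speckle_sigma
        speckle = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                                size=field_img.shape)
        field_img = field_img * speckle

    grey = fourth_root_rescale(field_img)

    masks = []
    records = []
    geometries = []
    for i, (spec, pixels) in enumerate(zip(specs, pixel_sets)):
        colour = spec.colour or _PALETTE[i % len(_PALETTE)]
        mask = LesionMask(pixels, colour, scan_id)
        masks.append(mask)
        records.append(_truth_record(spec, scan_id, lesion_id=str(i + 1)))
        geometries.append(measure_geometry(mask, calib))
    overlay = render_masks(grey, masks)

    return SyntheticScan(
        scan_id=scan_id,
        grey=grey,
        overlay=overlay,
        masks=tuple(masks),
        records=tuple(records),
        geometries=tuple(geometries),
        lesion_types=tuple(s.lesion_type for s in specs),
        specs=tuple(specs),
        calibration=calib,
        seed=seed,
    )


@dataclass(frozen=True)
class CohortDataset:
    """A generated cohort: one leading scan per patient, full truth."""

    scans: tuple[SyntheticScan, ...]
    seed: int
    parameters: Mapping[str, object]

    @property
    def records(self) -> list[GradingRecord]:
        return [r for scan in self.scans for r in scan.records]

    @property
    def geometries(self) -> list[LesionGeometry]:
        return [g for scan in self.scans for g in scan.geometries]

    @property
    def lesion_types(self) -> list[LesionType]:
        return [t for scan in self.scans for t in scan.lesion_types]

    @property
    def drawn_diameters_um(self) -> list[float]:
        """Diameters as drawn from the size distribution (pre-rasterization)."""
        return [s.diameter_um for scan in self.scans for s in scan.specs]

    @property
    def n_lesions(self) -> int:
        return sum(len(scan.masks) for scan in self.scans)


def _draw_brightness(rng: np.random.Generator) -> Brightness:
    return rng.choice(  # type: ignore[return-value]
        np.array([Brightness.LOW, Brightness.MODERATE, Brightness.HIGH]),
        p=[0.2, 0.6, 0.2])


def generate_cohort(
    n_patients: int = 100,
    size_distribution: tuple[float, float] = (DEFAULT_DIAMETER_MEANLOG,
                                              DEFAULT_DIAMETER_SDLOG),
    type_mix: Optional[Mapping[LesionType, float]] = None,
    seed: int = 0,
    model: Optional[RetinaModel] = None,
    lesions_per_scan_mean: float = 1.98,
    p_confluent_pair: float = 0.22,
) -> CohortDataset:
    """Generate a cohort of leading scans with ground truth.

    Per patient, one scan carries ``1 + Poisson(mean − 1)`` lesions
    (every leading scan shows at least one lesion; the default mean of
    1.98 lesions per scan reproduces a ≈198-lesion cohort at the
    default 100 patients). Lesion diameters are log-normal draws from
    ``size_distribution = (meanlog, sdlog)``, truncated to the rendered
    range [2 px, 60 px]. Per-scan lateral pixel width is drawn from
    Normal(11.27, 0.3) μm at a fixed axial pixel depth of 3.87 μm.
    Consecutive lesions are placed adjacently and flagged confluent
    with probability ``p_confluent_pair``.

    Deterministic for a fixed seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    meanlog, sdlog = size_distribution
    if sdlog < 0:
        raise ValueError(f"sdlog must be non-negative, got {sdlog}")
    mix = dict(type_mix) if type_mix is not None else dict(DEFAULT_TYPE_MIX)
    total = sum(mix.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"type proportions must sum to 1, got {total}")
    if lesions_per_scan_mean < 1:
        raise ValueError("lesions_per_scan_mean must be at least 1")

    model = model or RetinaModel()
    root = np.random.SeedSequence(seed)
    master_rng = np.random.default_rng(root)
    scan_seeds = root.spawn(n_patients)

    types = list(mix)
    probs = np.array([mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()

    scans = []
    for p in range(n_patients):
        scan_rng = np.random.default_rng(scan_seeds[p])
        scan_seed = int(scan_seeds[p].generate_state(1)[0] % (2 ** 31))
        scan_id = f"patient-{p + 1:03d}"
        width = max(1.0, float(scan_rng.normal(11.27, 0.3)))
        calib = ScanCalibration(pixel_width_um=width, pixel_depth_um=3.87)

        n_lesions = 1 + int(scan_rng.poisson(lesions_per_scan_mean - 1.0))
        specs: list[LesionSpec] = []
        cursor = 10 + int(scan_rng.integers(0, 20))  # left margin jitter
        for i in range(n_lesions):
            diameter_um = float(scan_rng.lognormal(meanlog, sdlog))
            d_px = _diameter_px(diameter_um, calib)
            if d_px > 60:  # truncate the far tail so placements fit
                d_px = 60
                diameter_um = d_px * calib.pixel_width_um
            confluent_with_prev = (
                i > 0 and scan_rng.random() < p_confluent_pair)
            gap = 0 if confluent_with_prev else 3 + int(scan_rng.integers(0, 15))
            first = cursor + gap
            last = first + d_px - 1
            if last >= model.n_cols - 10:
                break  # no room left on this scan
            lesion_type = types[int(scan_rng.choice(len(types), p=probs))]
            specs.append(LesionSpec(
                lesion_type=lesion_type,
                centre_col=first + d_px // 2,
                diameter_um=diameter_um,
                brightness=_draw_brightness(scan_rng),
                confluent=confluent_with_prev,
                drusen_ooze=bool(scan_rng.random() < 0.05),
            ))
            if confluent_with_prev and specs[-2:]:
                specs[-2] = replace(specs[-2], confluent=True)
            cursor = last + 1
        if not specs:  # degenerate: guarantee one small lesion
            specs = [LesionSpec(LesionType.DRUSEN, centre_col=60,
                                diameter_um=math.exp(meanlog))]
        scans.append(generate_bscan(model, specs, calib, seed=scan_seed,
                                    scan_id=scan_id))

    parameters = {
        "n_patients": n_patients,
        "diameter_meanlog": meanlog,
        "diameter_sdlog": sdlog,
        "type_mix": {t.value: mix[t] for t in types},
        "lesions_per_scan_mean": lesions_per_scan_mean,
        "p_confluent_pair": p_confluent_pair,
    }
    return CohortDataset(scans=tuple(scans), seed=seed, parameters=parameters)


def write_cohort(dataset: CohortDataset, outdir: Union[str, Path]) -> None:
    """Write a cohort to disk: images, records CSV, geometry CSV, manifest."""
    import imageio.v3 as iio
    import pandas as pd

    from .mask_geometry import geometry_table
    from .schema import save_records_csv

    outdir = Path(outdir)
    (outdir / "grey").mkdir(parents=True, exist_ok=True)
    (outdir / "overlay").mkdir(parents=True, exist_ok=True)
    geometry_frames = []
    for scan in dataset.scans:
        iio.imwrite(outdir / "grey" / f"{scan.scan_id}.png", scan.grey)
        iio.imwrite(outdir / "overlay" / f"{scan.scan_id}.png", scan.overlay)
        frame = geometry_table(list(scan.masks), scan.calibration,
                               [r.lesion_id for r in scan.records])
        frame.insert(2, "lesion_type",
                     [t.value for t in scan.lesion_types])
        geometry_frames.append(frame)
    save_records_csv(dataset.records, outdir / "records.csv")
    pd.concat(geometry_frames, ignore_index=True).to_csv(
        outdir / "geometry.csv", index=False)
    manifest = {"seed": dataset.seed, "parameters": dict(dataset.parameters),
                "n_scans": len(dataset.scans),
                "n_lesions": dataset.n_lesions}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                          encoding="utf-8")
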