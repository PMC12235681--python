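"""Lesion phenotypes: type classification, leading-scan selection, tracking.

In OCT, drusen and subretinal drusenoid deposits (SDDs) are told apart
by their position relative to the outer RPE complex: a deposit under
the RPE bulges it upward or breaks through (drusen), while a deposit
sitting on top of the RPE leaves it unaffected or bends it downward
(SDD). The operational classification therefore reads the graded RPE
state, with one override: a lesion consisting of hyper-reflective
material only (SP-03) is its own category regardless of the RPE state,
and a lesion whose RPE state could not be graded is unclassifiable.

For whole volume scans, the *leading drusen* is the lesion with the
maximal cutting area in any B-scan of the volume, and the *leading
scan* is the B-scan showing it — the canonical per-eye scan on which
all lesions are graded.

Tracking matches lesions between a baseline scan and a follow-up scan
at the identical position by annotation identity: the grader re-uses
the same mask colour / lesion id for the same lesion. No automated
spatial matching is attempted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

from .mask_geometry import LesionGeometry
from .schema import GradingRecord, LayerState, Progression, validate_record

__all__ = [
    "LesionType",
    "LeadingSelection",
    "TrackedPair",
    "TrackingError",
    "classify_lesion",
    "select_leading",
    "track_lesions",
    "check_progression_consistency",
]


class LesionType(enum.Enum):
    DRUSEN = "drusen"
    SDD = "sdd"
    HYPERREFLECTIVE_ONLY = "hyperreflective_only"
    UNGRADABLE = "ungradable"


def classify_lesion(record: GradingRecord) -> LesionType:
    """Operationally classify a graded lesion by RPE state and SP-03.

    Rules, in order of precedence:

    1. SP-03 ticked → ``HYPERREFLECTIVE_ONLY`` (even when the RPE is
       deformed: such a lesion is counted outside the drusen group).
    2. RPE bent down or unchanged (LAY-04A/B) → ``SDD``.
    3. RPE bent up or disrupted (LAY-04C/D) → ``DRUSEN``.
    4. RPE not gradable (LAY-04E) → ``UNGRADABLE``.

    The record must be valid; an invalid record is rejected.
    """
    violations = validate_record(record)
    if violations:
        raise ValueError(
            "cannot classify an invalid record: "
            + "; ".join(str(v) for v in violations))
    if record.hyperreflective_only:
        return LesionType.HYPERREFLECTIVE_ONLY
    if record.rpe in (LayerState.BENT_DOWN, LayerState.UNCHANGED):
        return LesionType.SDD
    if record.rpe in (LayerState.BENT_UP, LayerState.DISRUPTED):
        return LesionType.DRUSEN
    return LesionType.UNGRADABLE


@dataclass(frozen=True)
class LeadingSelection:
    """The leading drusen of a volume and the B-scan showing it."""

    scan_index: int
    lesion_id: str
    area_um2: float


AreaLike = Union[LesionGeometry, float, int]


def _area(value: AreaLike) -> float:
    if isinstance(value, LesionGeometry):
        return value.area_um2
    return float(value)


def select_leading(
    volume: Mapping[int, Mapping[str, AreaLike]]
) -> LeadingSelection:
    """Pick the lesion with the maximal cutting area across a volume.

    Parameters
    ----------
    volume : mapping
        ``{scan_index: {lesion_id: LesionGeometry or area_um2}}``.

    Ties are broken by the lowest scan index, then the lowest lesion id
    (string order), so the selection is deterministic.
    """
    best: Optional[LeadingSelection] = None
    for scan_index in sorted(volume):
        lesions = volume[scan_index]
        for lesion_id in sorted(lesions):
            area = _area(lesions[lesion_id])
            if best is None or area > best.area_um2:
                best = LeadingSelection(scan_index, str(lesion_id), area)
    if best is None:
        raise ValueError("cannot select a leading lesion from an empty volume")
    return best


@dataclass(frozen=True)
class TrackedPair:
    """One lesion's cutting area at baseline and follow-up.

    ``baseline_area_um2`` is 0 for lesions newly formed at follow-up
    (no baseline partner); ``has_baseline`` distinguishes a genuinely
    new lesion from one with a measured zero-area baseline.
    """

    lesion_id: str
    baseline_area_um2: float
    followup_area_um2: float
    delta_area_um2: float
    recorded_progression: Progression
    has_baseline: bool = True


class TrackingError(ValueError):
    """A follow-up grading contradicts the baseline annotation."""


_NEEDS_BASELINE = frozenset({
    Progression.GROWTH,
    Progression.STATIONARY,
    Progression.REMISSION_LAYERS_PRESERVED,
    Progression.REMISSION_LAYERS_DESTROYED,
})


def track_lesions(
    baseline: Mapping[str, AreaLike],
    followup: Mapping[str, AreaLike],
    followup_records: Optional[Mapping[str, GradingRecord]] = None,
) -> list[TrackedPair]:
    """Pair baseline and follow-up lesions by shared id and compute deltas.

    Correspondence is given by annotation identity (the grader masks
    the same lesion with the same colour/id at both visits). Every
    follow-up lesion yields one :class:`TrackedPair`; lesions with no
    baseline partner are treated as newly formed (baseline area 0,
    expected progression NEW). Area deltas are computed from the
    unrounded μm² values.

    Raises
    ------
    TrackingError
        If a follow-up record grades GROWTH/STATIONARY/REMISSION for a
        lesion that has no baseline partner — those progression states
        require an unambiguous identification with a baseline lesion.
    """
    followup_records = followup_records or {}
    pairs: list[TrackedPair] = []
    for lesion_id in sorted(followup, key=str):
        lesion_id = str(lesion_id)
        record = followup_records.get(lesion_id)
        progression = (record.progression if record is not None
                       else Progression.NOT_ASSESSED)
        has_baseline = lesion_id in {str(k) for k in baseline}
        if not has_baseline and progression in _NEEDS_BASELINE:
            raise TrackingError(
                f"lesion {lesion_id!r}: progression "
                f"{progression.name} requires a corresponding baseline "
                "lesion, but none is annotated")
        base_area = _area(baseline[lesion_id]) if has_baseline else 0.0
        follow_area = _area(followup[lesion_id])
        pairs.append(TrackedPair(
            lesion_id=lesion_id,
            baseline_area_um2=base_area,
            followup_area_um2=follow_area,
            delta_area_um2=follow_area - base_area,
            recorded_progression=progression,
            has_baseline=has_baseline,
        ))
    return pairs


def check_progression_consistency(
    pair: TrackedPair, growth_threshold_fraction: float = 0.10
) -> tuple[bool, str]:
    """Advisory check of the graded progression against measured areas.

    The grader's tick remains authoritative; this flags pairs for
    review when the relative area change contradicts it. With relative
    change ``q = delta / baseline``:

    * ``q > threshold`` → GROWTH expected,
    * ``|q| ≤ threshold`` → STATIONARY expected,
    * ``q < −threshold`` → partial/complete REMISSION expected,
    * no baseline partner → NEW expected.

    Returns ``(consistent, message)``; never raises for a mismatch.
    """
    recorded = pair.recorded_progression
    if recorded in (Progression.NOT_ASSESSED, Progression.UNCLEAR):
        return True, f"lesion {pair.lesion_id}: progression {recorded.name}, " \
                     "no expectation checked"
    if not pair.has_baseline or pair.baseline_area_um2 == 0.0:
        expected = {Progression.NEW}
        expectation = "NEW"
    else:
        q = pair.delta_area_um2 / pair.baseline_area_um2
        if q > growth_threshold_fraction:
            expected = {Progression.GROWTH}
            expectation = "GROWTH"
        elif q < -growth_threshold_fraction:
            expected = {Progression.REMISSION_LAYERS_PRESERVED,
                        Progression.REMISSION_LAYERS_DESTROYED}
            expectation = "REMISSION"
        else:
            expected = {Progression.STATIONARY}
            expectation = "STATIONARY"
    if recorded in expected:
        return True, (f"lesion {pair.lesion_id}: recorded {recorded.name} "
                      f"matches measured expectation {expectation}")
    return False, (f"lesion {pair.lesion_id}: recorded {recorded.name} but "
                   f"measured areas suggest {expectation} "
                   f"(baseline {pair.baseline_area_um2:.1f} μm², "
                   f"delta {pair.delta_area_um2:+.1f} μm²) — flag for review")


def phenotype_table(records: Iterable[GradingRecord],
                    geometries: Optional[Mapping[tuple[str, str],
                                                 LesionGeometry]] = None):
    """Per-lesion phenotype export: type plus metric sizes when available."""
    import pandas as pd

    rows = []
    for record in records:
        key = (record.scan_id, record.lesion_id)
        geom = geometries.get(key) if geometries else None
        rows.append({
            "scan_id": record.scan_id,
            "lesion_id": record.lesion_id,
            "lesion_type": classify_lesion(record).value,
            "area_um2": geom.area_um2 if geom else math.nan,
            "diameter_um": geom.diameter_um if geom else math.nan,
        })
    return pd.DataFrame(rows)


def tracking_table(pairs: Iterable[TrackedPair],
                   growth_threshold_fraction: float = 0.10):
    """Tracking export with per-pair advisory consistency flags."""
    import pandas as pd

    rows = []
    for pair in pairs:
        consistent, message = check_progression_consistency(
            pair, growth_threshold_fraction)
        rows.append({
            "lesion_id": pair.lesion_id,
            "baseline_area_um2": pair.baseline_area_um2,
            "followup_area_um2": pair.followup_area_um2,
            "delta_area_um2": pair.delta_area_um2,
            "recorded_progression": pair.recorded_progression.name,
            "consistent": consistent,
            "note": message,
        })
    return pd.DataFrame(rows)
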