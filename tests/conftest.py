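import math

import pytest

from earlyamdrate.oct_preprocess import ScanCalibration
from earlyamdrate.schema import (Brightness, GradingRecord, LayerState,
                                 Separability)
from earlyamdrate.synthdata import generate_cohort

S = LayerState


def make_record(scan_id="s1", lesion_id="1", **kwargs) -> GradingRecord:
    """A fully graded, valid record with overridable fields."""
    defaults = dict(
        scan_gradable=True,
        elm=S.UNCHANGED, ez=S.BENT_UP, iz=S.BENT_UP, rpe=S.BENT_UP,
        bm=S.UNCHANGED,
        iz_rpe_separable=Separability.YES,
        brightness=Brightness.MODERATE,
    )
    defaults.update(kwargs)
    return GradingRecord(scan_id=scan_id, lesion_id=lesion_id, **defaults)


#: questionnaires transcribed from worked single-lesion grading examples:
#: small drusen, confluent drusen, layer-disrupting drusen, SDD, lesion
#: with trailing hyper-reflective material, hyper-reflective-only lesion
WORKED_EXAMPLES = {
    "small_drusen": make_record(
        elm=S.UNCHANGED, ez=S.BENT_UP, iz=S.BENT_UP, rpe=S.BENT_UP,
        bm=S.UNCHANGED, brightness=Brightness.MODERATE),
    "confluent_drusen": make_record(
        elm=S.BENT_UP, ez=S.BENT_UP, iz=S.BENT_UP, rpe=S.BENT_UP,
        bm=S.UNCHANGED, brightness=Brightness.LOW, confluent=True),
    "disrupting_drusen": make_record(
        elm=S.DISRUPTED, ez=S.DISRUPTED, iz=S.DISRUPTED, rpe=S.DISRUPTED,
        bm=S.UNCHANGED, brightness=Brightness.MODERATE),
    "sdd": make_record(
        elm=S.BENT_UP, ez=S.DISRUPTED, iz=S.UNCHANGED, rpe=S.UNCHANGED,
        bm=S.UNCHANGED, brightness=Brightness.MODERATE),
    "trailing_material": make_record(
        elm=S.DISRUPTED, ez=S.DISRUPTED, iz=S.DISRUPTED, rpe=S.DISRUPTED,
        bm=S.NOT_GRADABLE, brightness=Brightness.MODERATE,
        confluent=True, drusen_ooze=True),
    "hyperreflective_focus": make_record(
        elm=S.BENT_UP, ez=S.BENT_UP, iz=S.BENT_UP, rpe=S.BENT_UP,
        bm=S.UNCHANGED, brightness=Brightness.HIGH,
        hyperreflective_only=True),
}

#: cutting areas (μm²) of the five-lesion tracking example, by lesion id
TRACKING_BASELINE = {"1": 2740.0, "2": 1566.0, "3": 2001.0, "4": 7307.0,
                     "5": 3262.0}
TRACKING_FOLLOWUP = {"1": 3219.0, "2": 9917.0, "3": 2740.0, "4": 13397.0,
                     "5": 14093.0}

#: cohort size-distribution defaults: median diameter 154.8 μm, sdlog 0.6
DIAMETER_MEANLOG = math.log(154.8)
DIAMETER_SDLOG = 0.6


@pytest.fixture(scope="session")
def calib() -> ScanCalibration:
    """Mean study calibration: 11.27 μm lateral × 3.87 μm axial."""
    return ScanCalibration(pixel_width_um=11.27, pixel_depth_um=3.87)


@pytest.fixture(scope="session")
def cohort100():
    """A 100-patient synthetic cohort, shared across tests (read-only)."""
    return generate_cohort(n_patients=100, seed=20260922)
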