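"""Questionnaire data model for single Early-AMD lesion grading.

A grading record describes one lesion in one OCT B-scan: general scan
properties (gradability, late-AMD signs, follow-up status), the state of
the five outer-retinal layers/reflectivity bands around the lesion
(ELM, EZ, IZ, outer RPE complex, Bruch's membrane), whether IZ and RPE
are separable around the lesion, the lesion's brightness, three special
flags (confluence, trailing hyper-reflective material a.k.a. drusen
ooze, hyper-reflective material only), and — for follow-up scans — the
state of progression relative to baseline.

Every tickable field carries a literal field code (``GEN-01`` …
``PRO-06``) used verbatim as a column name in CSV/JSON serialization,
so grading sheets can be exchanged with external readout software.
Validation returns lists of violations instead of raising, so a whole
batch of gradings can be checked and reported in one pass.
"""

from __future__ import annotations

import csv
import enum
import io
import json
from collections import Counter
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "LayerState",
    "Brightness",
    "Separability",
    "Progression",
    "GradingRecord",
    "Violation",
    "OccupancyTable",
    "ParseError",
    "validate_record",
    "tabulate_occupancies",
    "record_to_row",
    "row_to_record",
    "records_to_rows",
    "rows_to_records",
    "save_records_csv",
    "load_records_csv",
    "save_records_json",
    "load_records_json",
    "all_field_codes",
    "LAYER_FIELDS",
]


class LayerState(enum.Enum):
    """State of one retinal layer/band around a lesion.

    The enum value is the field-code suffix: ``LAY-04C`` means the outer
    RPE complex is bent or bulged upwards but still connected.
    """

    BENT_DOWN = "A"      # bent or bulged downwards but still connected
    UNCHANGED = "B"      # unchanged and intact
    BENT_UP = "C"        # bent or bulged upwards but still connected
    DISRUPTED = "D"      # disrupted or destroyed
    NOT_GRADABLE = "E"   # state/geometry cannot be clearly assessed


class Brightness(enum.Enum):
    """Lesion brightness category (fields BRI-01 … BRI-05)."""

    LOW = 1
    MODERATE = 2
    HIGH = 3
    OTHER = 4            # e.g. brightness varies strongly throughout
    NOT_GRADABLE = 5

    @property
    def code(self) -> str:
        return f"BRI-0{self.value}"


class Separability(enum.Enum):
    """Whether IZ and outer RPE can be clearly separated around the lesion."""

    YES = "yes"
    NO = "no"
    UNASSESSED = "unassessed"


class Progression(enum.Enum):
    """State of progression at follow-up (fields PRO-01 … PRO-06).

    ``NOT_ASSESSED`` represents the absence of a tick (baseline scans,
    or cohorts where progression was not graded), so occupancy tables
    remain representable for such cohorts.
    """

    NEW = 1
    GROWTH = 2
    STATIONARY = 3
    REMISSION_LAYERS_PRESERVED = 4
    REMISSION_LAYERS_DESTROYED = 5
    UNCLEAR = 6
    NOT_ASSESSED = 0

    @property
    def code(self) -> Optional[str]:
        return None if self is Progression.NOT_ASSESSED else f"PRO-0{self.value}"


#: attribute name -> layer field prefix, in anatomical order (inner to outer)
LAYER_FIELDS: Mapping[str, str] = {
    "elm": "LAY-01",
    "ez": "LAY-02",
    "iz": "LAY-03",
    "rpe": "LAY-04",
    "bm": "LAY-05",
}

_GEN_FIELDS: Mapping[str, str] = {
    "scan_gradable": "GEN-01",
    "dry_late_amd": "GEN-02",
    "wet_late_amd": "GEN-03",
    "is_followup": "GEN-04",
}

_SP_FIELDS: Mapping[str, str] = {
    "confluent": "SP-01",
    "drusen_ooze": "SP-02",
    "hyperreflective_only": "SP-03",
}

_LAYER_SUFFIXES = "ABCDE"


def all_field_codes() -> list[str]:
    """All tickable field codes, in questionnaire order."""
    codes = list(_GEN_FIELDS.values())
    for prefix in LAYER_FIELDS.values():
        codes.extend(f"{prefix}{s}" for s in _LAYER_SUFFIXES)
    codes.append("INSEP")
    codes.extend(b.code for b in Brightness)
    codes.extend(_SP_FIELDS.values())
    codes.extend(f"PRO-0{i}" for i in range(1, 7))
    return codes


@dataclass(frozen=True)
class Violation:
    """One rule violation in a grading record; data, not an exception."""

    field_codes: tuple[str, ...]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{', '.join(self.field_codes)}] {self.message}"


@dataclass(frozen=True)
class GradingRecord:
    """One lesion's completed questionnaire.

    Layer states may be ``None`` to represent a sheet where no box was
    ticked for that layer; :func:`validate_record` flags this. A record
    compares equal to another iff every graded field agrees.
    """

    scan_id: str
    lesion_id: str
    scan_gradable: bool = True                      # GEN-01
    dry_late_amd: bool = False                      # GEN-02
    wet_late_amd: bool = False                      # GEN-03
    is_followup: bool = False                       # GEN-04
    elm: Optional[LayerState] = None                # LAY-01
    ez: Optional[LayerState] = None                 # LAY-02
    iz: Optional[LayerState] = None                 # LAY-03
    rpe: Optional[LayerState] = None                # LAY-04
    bm: Optional[LayerState] = None                 # LAY-05
    iz_rpe_separable: Separability = Separability.UNASSESSED  # INSEP
    brightness: Optional[Brightness] = None         # BRI-01…05
    confluent: bool = False                         # SP-01
    drusen_ooze: bool = False                       # SP-02
    hyperreflective_only: bool = False              # SP-03
    progression: Progression = Progression.NOT_ASSESSED  # PRO-01…06

    def layer_states(self) -> dict[str, Optional[LayerState]]:
        return {name: getattr(self, name) for name in LAYER_FIELDS}


def validate_record(record: GradingRecord) -> list[Violation]:
    """Check a grading record against the instrument's consistency rules.

    Returns an empty list iff the record is valid; otherwise one
    :class:`Violation` per broken rule, each naming the offending field
    code(s). Pure function: the record is never modified.
    """
    violations: list[Violation] = []

    if record.scan_gradable:
        for name, prefix in LAYER_FIELDS.items():
            state = getattr(record, name)
            if not isinstance(state, LayerState):
                violations.append(Violation(
                    (prefix,),
                    f"exactly one state (suffix A-E) must be ticked for {name.upper()}",
                ))
        if not isinstance(record.brightness, Brightness):
            violations.append(Violation(
                tuple(b.code for b in Brightness),
                "exactly one brightness category must be ticked",
            ))
    else:
        # Non-gradable scan: all lesion-level fields must be unset or
        # explicitly not-gradable.
        for name, prefix in LAYER_FIELDS.items():
            state = getattr(record, name)
            if state not in (None, LayerState.NOT_GRADABLE):
                violations.append(Violation(
                    ("GEN-01", f"{prefix}{state.value}"),
                    f"{name.upper()} graded although the scan is not gradable",
                ))
        if record.brightness not in (None, Brightness.NOT_GRADABLE):
            violations.append(Violation(
                ("GEN-01", record.brightness.code),
                "brightness graded although the scan is not gradable",
            ))
        if record.iz_rpe_separable is not Separability.UNASSESSED:
            violations.append(Violation(
                ("GEN-01", "INSEP"),
                "IZ/RPE separability graded although the scan is not gradable",
            ))
        for name, code in _SP_FIELDS.items():
            if getattr(record, name):
                violations.append(Violation(
                    ("GEN-01", code),
                    "special property ticked although the scan is not gradable",
                ))
        if record.progression is not Progression.NOT_ASSESSED:
            violations.append(Violation(
                ("GEN-01", record.progression.code or "PRO"),
                "progression graded although the scan is not gradable",
            ))

    if record.progression is not Progression.NOT_ASSESSED and not record.is_followup:
        violations.append(Violation(
            ("GEN-04", record.progression.code or "PRO"),
            "progression may only be assessed for follow-up scans",
        ))

    return violations


@dataclass(frozen=True)
class OccupancyTable:
    """Tick counts per field code over a record collection."""

    counts: Mapping[str, int]
    n_records: int

    def __getitem__(self, code: str) -> int:
        return self.counts[code]

    def to_frame(self):
        """Two-column DataFrame (field_code, count), questionnaire order."""
        import pandas as pd

        return pd.DataFrame(
            {"field_code": list(self.counts), "count": list(self.counts.values())}
        )


def tabulate_occupancies(records: Iterable[GradingRecord]) -> OccupancyTable:
    """Count, for every questionnaire field, how many records tick it.

    All records must be individually valid; an invalid record aborts the
    tabulation with a :class:`ValueError` naming its index. The result
    is independent of record order.
    """
    counts: Counter[str] = Counter({code: 0 for code in all_field_codes()})
    n = 0
    for idx, record in enumerate(records):
        violations = validate_record(record)
        if violations:
            raise ValueError(
                f"record {idx} (scan {record.scan_id!r}, lesion "
                f"{record.lesion_id!r}) is invalid: "
                + "; ".join(str(v) for v in violations)
            )
        n += 1
        for attr, code in _GEN_FIELDS.items():
            if getattr(record, attr):
                counts[code] += 1
        for attr, prefix in LAYER_FIELDS.items():
            state = getattr(record, attr)
            if state is not None:
                counts[f"{prefix}{state.value}"] += 1
            else:  # only possible for non-gradable scans
                counts[f"{prefix}E"] += 1
        if record.iz_rpe_separable is Separability.YES:
            counts["INSEP"] += 1
        if record.brightness is not None:
            counts[record.brightness.code] += 1
        elif not record.scan_gradable:
            counts[Brightness.NOT_GRADABLE.code] += 1
        for attr, code in _SP_FIELDS.items():
            if getattr(record, attr):
                counts[code] += 1
        if record.progression.code is not None:
            counts[record.progression.code] += 1
    return OccupancyTable(counts=dict(counts), n_records=n)


# ---------------------------------------------------------------------------
# Serialization: one row per lesion, columns = literal field codes.
# Booleans are written as 0/1; INSEP is 0/1 or empty (unassessed); layer
# states and brightness/progression are one-hot over their field codes.
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Raised when a serialized record cannot be interpreted.

    Carries the offending row index (0-based, excluding the header) and
    column name where available.
    """

    def __init__(self, message: str, row: Optional[int] = None,
                 column: Optional[str] = None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))


_ID_COLUMNS = ("scan_id", "lesion_id")


def record_to_row(record: GradingRecord) -> dict[str, str]:
    """Serialize one record to a flat string-valued mapping."""
    row: dict[str, str] = {code: "0" for code in all_field_codes()}
    row["scan_id"] = record.scan_id
    row["lesion_id"] = record.lesion_id
    for attr, code in _GEN_FIELDS.items():
        row[code] = "1" if getattr(record, attr) else "0"
    for attr, prefix in LAYER_FIELDS.items():
        state = getattr(record, attr)
        if state is not None:
            row[f"{prefix}{state.value}"] = "1"
    row["INSEP"] = {
        Separability.YES: "1",
        Separability.NO: "0",
        Separability.UNASSESSED: "",
    }[record.iz_rpe_separable]
    if record.brightness is not None:
        row[record.brightness.code] = "1"
    for attr, code in _SP_FIELDS.items():
        row[code] = "1" if getattr(record, attr) else "0"
    if record.progression.code is not None:
        row[record.progression.code] = "1"
    return row


def _parse_bool(value: str, row: int, column: str) -> bool:
    if value == "1":
        return True
    if value == "0":
        return False
    raise ParseError(f"expected 0 or 1, got {value!r}", row=row, column=column)


def _parse_onehot(row_data: Mapping[str, str], codes: Sequence[str],
                  row: int, required: bool) -> Optional[str]:
    ticked = [c for c in codes if _parse_bool(row_data.get(c, "0"), row, c)]
    if len(ticked) > 1:
        raise ParseError("more than one mutually exclusive field ticked: "
                         + ", ".join(ticked), row=row, column=ticked[1])
    if not ticked:
        if required:
            raise ParseError("no state ticked among " + ", ".join(codes), row=row,
                             column=codes[0])
        return None
    return ticked[0]


def row_to_record(row_data: Mapping[str, str], row: int = 0) -> GradingRecord:
    """Parse one serialized row back into a :class:`GradingRecord`."""
    for col in _ID_COLUMNS:
        if col not in row_data:
            raise ParseError(f"missing identifier column", row=row, column=col)

    gen = {attr: _parse_bool(str(row_data.get(code, "0")), row, code)
           for attr, code in _GEN_FIELDS.items()}
    gradable = gen["scan_gradable"]

    layers: dict[str, Optional[LayerState]] = {}
    for attr, prefix in LAYER_FIELDS.items():
        codes = [f"{prefix}{s}" for s in _LAYER_SUFFIXES]
        ticked = _parse_onehot(row_data, codes, row, required=gradable)
        layers[attr] = LayerState(ticked[-1]) if ticked else None

    insep_raw = str(row_data.get("INSEP", ""))
    if insep_raw == "":
        insep = Separability.UNASSESSED
    else:
        insep = Separability.YES if _parse_bool(insep_raw, row, "INSEP") \
            else Separability.NO

    bri_codes = [b.code for b in Brightness]
    bri = _parse_onehot(row_data, bri_codes, row, required=gradable)
    brightness = Brightness(int(bri[-1])) if bri else None

    sp = {attr: _parse_bool(str(row_data.get(code, "0")), row, code)
          for attr, code in _SP_FIELDS.items()}

    pro_codes = [f"PRO-0{i}" for i in range(1, 7)]
    pro = _parse_onehot(row_data, pro_codes, row, required=False)
    progression = Progression(int(pro[-1])) if pro else Progression.NOT_ASSESSED

    return GradingRecord(
        scan_id=str(row_data["scan_id"]),
        lesion_id=str(row_data["lesion_id"]),
        **gen,
        **layers,
        iz_rpe_separable=insep,
        brightness=brightness,
        **sp,
        progression=progression,
    )


def records_to_rows(records: Iterable[GradingRecord]) -> list[dict[str, str]]:
    return [record_to_row(r) for r in records]


def rows_to_records(rows: Iterable[Mapping[str, str]]) -> list[GradingRecord]:
    return [row_to_record(row_data, row=i) for i, row_data in enumerate(rows)]


def _csv_header() -> list[str]:
    return list(_ID_COLUMNS) + all_field_codes()


def save_records_csv(records: Iterable[GradingRecord],
                     path: Union[str, Path, io.TextIOBase]) -> None:
    """Write records as RFC-4180 CSV, one row per lesion, UTF-8."""
    header = _csv_header()
    rows = records_to_rows(records)

    def _write(handle) -> None:
        writer = csv.DictWriter(handle, fieldnames=header, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)

    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8", newline="") as handle:
            _write(handle)
    else:
        _write(path)


def load_records_csv(path: Union[str, Path, io.TextIOBase]) -> list[GradingRecord]:
    """Read records from CSV; unknown or duplicate columns are errors."""
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8", newline="") as handle:
            rows = list(csv.reader(handle))
    else:
        rows = list(csv.reader(path))
    if not rows:
        raise ParseError("empty file: header row missing")
    header = rows[0]
    known = set(_csv_header())
    seen: set[str] = set()
    for col in header:
        if col not in known:
            raise ParseError("unknown column", column=col)
        if col in seen:
            raise ParseError("duplicate field code", column=col)
        seen.add(col)
    records = []
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise ParseError(
                f"expected {len(header)} cells, got {len(row)}", row=i)
        records.append(row_to_record(dict(zip(header, row)), row=i))
    return records


def save_records_json(records: Iterable[GradingRecord],
                      path: Union[str, Path]) -> None:
    """Write records as a JSON array of flat objects (same keys as CSV)."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(records_to_rows(records), handle, indent=1)


def load_records_json(path: Union[str, Path]) -> list[GradingRecord]:
    with open(path, "r", encoding="utf-8") as handle:
        data = json.load(handle)
    if not isinstance(data, list):
        raise ParseError("expected a JSON array of record objects")
    return [row_to_record({k: str(v) for k, v in obj.items()}, row=i)
            for i, obj in enumerate(data)]
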