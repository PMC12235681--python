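"""Questionnaire model: validation rules, occupancies, serialization."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from earlyamdrate.schema import (Brightness, GradingRecord, LayerState,
                                 ParseError, Progression, Separability,
                                 all_field_codes, load_records_csv,
                                 record_to_row, row_to_record,
                                 save_records_csv, tabulate_occupancies,
                                 validate_record)
from conftest import WORKED_EXAMPLES, make_record


class TestValidateRecord:
    @pytest.mark.parametrize("name", sorted(WORKED_EXAMPLES))
    def test_worked_examples_are_valid(self, name):
        assert validate_record(WORKED_EXAMPLES[name]) == []

    def test_missing_layer_state_is_flagged(self):
        record = make_record(iz=None)
        violations = validate_record(record)
        assert len(violations) == 1
        assert "LAY-03" in violations[0].field_codes

    def test_missing_brightness_is_flagged(self):
        violations = validate_record(make_record(brightness=None))
        assert len(violations) == 1
        assert "BRI-01" in violations[0].field_codes

    def test_progression_requires_followup(self):
        record = make_record(is_followup=False,
                             progression=Progression.GROWTH)
        violations = validate_record(record)
        assert len(violations) == 1
        assert set(violations[0].field_codes) == {"GEN-04", "PRO-02"}

    def test_progression_allowed_on_followup(self):
        record = make_record(is_followup=True, progression=Progression.GROWTH)
        assert validate_record(record) == []

    def test_nongradable_scan_forbids_lesion_fields(self):
        record = make_record(scan_gradable=False)  # layers still graded
        violations = validate_record(record)
        offending = {code for v in violations for code in v.field_codes}
        assert "GEN-01" in offending
        assert any(code.startswith("LAY") for code in offending)

    def test_nongradable_scan_with_unset_fields_is_valid(self):
        record = GradingRecord(scan_id="s", lesion_id="1",
                               scan_gradable=False)
        assert validate_record(record) == []

    def test_validation_is_pure(self):
        record = make_record()
        before = record
        validate_record(record)
        assert record == before
        assert validate_record(record) == validate_record(record)


class TestOccupancies:
    def test_direct_counts(self):
        records = [make_record(lesion_id=str(i), brightness=b)
                   for i, b in enumerate([Brightness.MODERATE,
                                          Brightness.MODERATE,
                                          Brightness.LOW])]
        table = tabulate_occupancies(records)
        assert table["BRI-02"] == 2
        assert table["BRI-01"] == 1
        assert table["BRI-03"] == 0
        assert table.n_records == 3

    def test_empty_collection(self):
        table = tabulate_occupancies([])
        assert table.n_records == 0
        assert all(count == 0 for count in table.counts.values())

    def test_confluent_count_on_synthetic_cohort(self):
        # 198 records of which exactly 44 carry the confluence flag
        records = [make_record(lesion_id=str(i), confluent=(i < 44))
                   for i in range(198)]
        table = tabulate_occupancies(records)
        assert table["SP-01"] == 44
        assert table.n_records == 198

    def test_layer_counts_sum_to_n(self):
        records = [make_record(lesion_id=str(i),
                               rpe=list(LayerState)[i % 5])
                   for i in range(23)]
        table = tabulate_occupancies(records)
        for prefix in ("LAY-01", "LAY-02", "LAY-03", "LAY-04", "LAY-05"):
            total = sum(table[f"{prefix}{s}"] for s in "ABCDE")
            assert total == table.n_records
        assert sum(table[b.code] for b in Brightness) == table.n_records

    def test_order_independence(self):
        records = [make_record(lesion_id=str(i), confluent=i % 2 == 0)
                   for i in range(10)]
        forward = tabulate_occupancies(records)
        backward = tabulate_occupancies(records[::-1])
        assert forward.counts == backward.counts

    def test_invalid_record_rejected_with_index(self):
        records = [make_record(), make_record(brightness=None)]
        with pytest.raises(ValueError, match="record 1"):
            tabulate_occupancies(records)


# -- serialization ----------------------------------------------------------

_layer_state = st.sampled_from(list(LayerState))


@st.composite
def valid_records(draw):
    followup = draw(st.booleans())
    progression = (draw(st.sampled_from(list(Progression))) if followup
                   else Progression.NOT_ASSESSED)
    return GradingRecord(
        scan_id=draw(st.text(
            alphabet=st.characters(min_codepoint=48, max_codepoint=122),
            min_size=1, max_size=8)),
        lesion_id=str(draw(st.integers(1, 99))),
        scan_gradable=True,
        dry_late_amd=draw(st.booleans()),
        wet_late_amd=draw(st.booleans()),
        is_followup=followup,
        elm=draw(_layer_state), ez=draw(_layer_state), iz=draw(_layer_state),
        rpe=draw(_layer_state), bm=draw(_layer_state),
        iz_rpe_separable=draw(st.sampled_from(list(Separability))),
        brightness=draw(st.sampled_from(list(Brightness))),
        confluent=draw(st.booleans()),
        drusen_ooze=draw(st.booleans()),
        hyperreflective_only=draw(st.booleans()),
        progression=progression,
    )


class TestSerialization:
    @settings(max_examples=60, derandomize=True)
    @given(record=valid_records())
    def test_roundtrip_identity(self, record):
        assert row_to_record(record_to_row(record)) == record

    def test_worked_example_roundtrips_through_csv(self):
        records = list(WORKED_EXAMPLES.values())
        buffer = io.StringIO()
        save_records_csv(records, buffer)
        buffer.seek(0)
        assert load_records_csv(buffer) == records

    def test_count_preserved_over_csv(self, tmp_path):
        records = [make_record(lesion_id=str(i)) for i in range(198)]
        path = tmp_path / "records.csv"
        save_records_csv(records, path)
        assert len(load_records_csv(path)) == 198

    def test_no_layer_tick_is_parse_error(self):
        row = record_to_row(make_record())
        for suffix in "ABCDE":
            row[f"LAY-01{suffix}"] = "0"
        with pytest.raises(ParseError, match="LAY-01"):
            row_to_record(row)

    def test_double_brightness_tick_is_parse_error(self):
        row = record_to_row(make_record())
        row["BRI-01"] = "1"
        row["BRI-03"] = "1"
        with pytest.raises(ParseError, match="BRI"):
            row_to_record(row)

    def test_unknown_and_duplicate_columns_rejected(self):
        header = ",".join(["scan_id", "lesion_id"] + all_field_codes())
        bogus = io.StringIO(header.replace("INSEP", "BOGUS") + "\n")
        with pytest.raises(ParseError, match="BOGUS"):
            load_records_csv(bogus)
        doubled = io.StringIO(header + ",GEN-01\n")
        with pytest.raises(ParseError, match="duplicate"):
            load_records_csv(doubled)

    def test_non_boolean_cell_names_row_and_column(self):
        row = record_to_row(make_record())
        row["SP-01"] = "maybe"
        with pytest.raises(ParseError, match="SP-01"):
            row_to_record(row, row=5)
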