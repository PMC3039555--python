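"""Field-level identifier cleaning and record-level policy rules."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import idlink as il
from idlink.cleaning import CleaningConfig, RawRecord

CFG = CleaningConfig(today=dt.date(2026, 9, 17))


@pytest.mark.parametrize(
    "value,is_forename,expected",
    [
        ("De Souza", False, "DESOUZA"),  # uppercase + symbol/whitespace removal
        ("J.", False, None),  # single letter after symbol removal
        ("Baby", True, None),  # placeholder forename
        ("BABY OF SMITH", True, None),  # placeholder appears as substring
        ("Baby", False, "BABY"),  # surnames are not screened for placeholders
        ("O'Brien", False, "OBRIEN"),
        ("  ", False, None),
        (None, False, None),
        ("12", False, None),  # non-alphabetic
        ("Twin A", True, None),
    ],
)
def test_clean_name(value, is_forename, expected):
    assert il.clean_name(value, is_forename=is_forename) == expected


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.text(max_size=20))
def test_clean_name_invariants(value):
    out = il.clean_name(value)
    assert out is None or (out.isalpha() and out.isupper() and len(out) >= 2)
    # idempotence at the field level
    assert il.clean_name(out) == out or out is None


@pytest.mark.parametrize(
    "forename,surname,expected",
    [
        ("SMITH", "DAVID", ("DAVID", "SMITH")),  # reversed pair put right
        ("DAVID", "WILSON", ("DAVID", "WILSON")),  # forename known: untouched
        ("XQZR", "YTWP", ("XQZR", "YTWP")),  # neither known: no swap
        (None, "DAVID", (None, "DAVID")),  # null input: unchanged
    ],
)
def test_maybe_swap_names(forename, surname, expected):
    reference = {"DAVID", "JOHN", "MARY"}
    assert il.maybe_swap_names(forename, surname, reference) == expected


@pytest.mark.parametrize(
    "value,expected",
    [("f", "F"), ("M", "M"), ("u", "U"), ("1", None), ("MALE", "M"), ("Female", "F"), ("  ", None)],
)
def test_clean_sex(value, expected):
    assert il.clean_sex(value) == expected


@pytest.mark.parametrize(
    "value,expected",
    [
        # Modulus-11 verdicts computed by hand with weights 10..2:
        ("4010232137", "4010232137"),  # weighted sum 92 -> check 7, matches
        ("5170231111", None),  # weighted sum 151 -> check 3, printed 1
        ("3319004037", None),  # weighted sum 150 -> check 4, printed 7
        ("123456789", None),  # 9 digits
        ("40102321370", None),  # 11 digits
        ("1111111111", None),  # passes mod-11 (check 1) but blacklisted
        (" 401 023 2137 ", "4010232137"),  # whitespace stripped before checking
        (None, None),
    ],
)
def test_validate_nhs_number(value, expected):
    assert il.validate_nhs_number(value) == expected


@pytest.mark.parametrize(
    "value,code,expected",
    [
        ("123456", "A", "A:123456"),
        ("99999999", None, None),  # out of range 1..10^7
        ("4496644", None, "4496644"),
        ("A:123456", None, "A:123456"),  # already prefixed: idempotent
        (" 44 96644 ", None, "4496644"),
        ("0", None, None),  # below range
        ("ABC", None, None),  # non-numeric
        (None, "A", None),
    ],
)
def test_clean_hospital_number(value, code, expected):
    assert il.clean_hospital_number(value, code) == expected


def test_clean_hospital_number_check_digit_stripping():
    assert il.clean_hospital_number("1234567", strip_check_digit=True) == "123456"


@pytest.mark.parametrize(
    "value,expected",
    [
        ("14061940", "1940-06-14"),  # ddmmyyyy wire format
        ("01011850", None),  # before the 1860 floor
        ("01013025", None),  # future
        ("1969-01-20", None if False else "1969-01-20"),  # ISO accepted -> idempotent
        ("31022000", None),  # impossible date
        ("notadate", None),
        (None, None),
    ],
)
def test_clean_date(value, expected):
    assert il.clean_date(value, today=dt.date(2026, 9, 17)) == expected


def test_clean_record_suppressed_clinic():
    raw = RawRecord(
        record_id=1, surname="WILSON", forename="DAVID", sex="M",
        birthdate="14061940", nhs_number="4010232137", hospital_number="4496644",
        clinic_code="GUM",
    )
    rec = il.clean_record(raw, CFG)
    assert rec.suppressed
    assert rec.surname is rec.forename is rec.nhs_number is rec.hospital_number is None


def test_clean_record_worked_row():
    raw = RawRecord(
        record_id=1, surname="Wilson", forename="David", sex="M",
        birthdate="14061940", hospital_number="4496644",
    )
    rec = il.clean_record(raw, CFG)
    assert (rec.surname, rec.forename, rec.sex) == ("WILSON", "DAVID", "M")
    assert rec.birthdate == "1940-06-14"
    assert rec.hospital_number == "4496644"
    assert rec.nhs_number is None


def test_clean_record_empty_and_test_patient():
    assert vars(il.clean_record(RawRecord(record_id=9), CFG))["surname"] is None
    rec = il.clean_record(RawRecord(record_id=2, surname="ZZTEST", forename="ANNA"), CFG)
    assert rec.surname is None and rec.forename is None


def test_clean_frame_idempotent_and_audited():
    raw = pd.DataFrame(
        [
            {"record_id": 1, "surname": "de Souza", "forename": "Baby", "sex": "male",
             "birthdate": "14061940", "nhs_number": "5170231111", "hospital_number": "4496644"},
            {"record_id": 2, "surname": "WILSON", "forename": "DAVID", "sex": "M",
             "birthdate": "20011969", "nhs_number": "4010232137", "hospital_number": "123456",
             "hospital_code": "A"},
        ]
    )
    cleaned, audit = il.clean_frame(raw, CFG, with_audit=True)
    # every surviving NHS number passes validation
    for v in cleaned["nhs_number"].dropna():
        assert il.validate_nhs_number(v) == v
    # audit captured the nulled placeholder forename and invalid NHS number
    actions = {(r["record_id"], r["field"]): r["action"] for _, r in audit.iterrows()}
    assert actions[(1, "forename")] == "nulled"
    assert actions[(1, "nhs_number")] == "nulled"
    # re-cleaning the cleaned output changes nothing (idempotence)
    again = il.clean_frame(cleaned, CFG)
    pd.testing.assert_frame_equal(cleaned, again)


def test_cleaning_never_invents_values():
    raw = pd.DataFrame(
        [{"record_id": i, "surname": s, "forename": f, "sex": x, "birthdate": b,
          "nhs_number": n, "hospital_number": h}
         for i, (s, f, x, b, n, h) in enumerate(
             [("Smith", "Ann", "F", "01011990", "4010232137", "100"),
              (None, None, None, None, None, None),
              ("Lee", "J.", "q", "31131999", "123", "99999999")])]
    )
    cleaned = il.clean_frame(raw, CFG)
    for col in ["surname", "forename", "nhs_number", "hospital_number"]:
        for rawv, cleanv in zip(raw[col], cleaned[col]):
            if cleanv is not None:
                assert rawv is not None  # non-null output requires non-null input


def test_reference_forenames_built_from_data():
    frame = pd.DataFrame(
        {"source": ["PAS"] * 4 + ["LIMS"], "forename": ["David", "DAVID", "Mary", "Mary", "Zed"]}
    )
    ref = il.reference_forenames(frame, sources=("PAS",), min_count=2)
    assert ref == {"DAVID", "MARY"}
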