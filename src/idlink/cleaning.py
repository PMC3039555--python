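"""Identifier quality control.

Hospital record systems accumulate malformed identifiers: placeholder forenames
("BABY"), swapped name fields, NHS numbers failing their Modulus-11 check digit,
out-of-range hospital numbers, impossible dates. Every field-level cleaner here
maps a raw value to either a normalised value or ``None`` — cleaning never
raises on bad data, it nulls it. Records from clinics whose identity must be
suppressed by policy (genito-urinary medicine, occupational health) have *all*
identifiers nulled.

The canonical cleaned representation is:

* names: uppercase A-Z only, length >= 2
* sex: one of ``M`` / ``F`` / ``U``
* dates: ISO ``YYYY-MM-DD`` strings within [1860-01-01, today]
* NHS number: 10-digit string passing the Modulus-11 check
* hospital number: digit string, optionally prefixed ``CODE:`` to disambiguate
  numbers issued independently by different hospitals
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CleaningConfig",
    "RawRecord",
    "CleanRecord",
    "clean_name",
    "maybe_swap_names",
    "clean_sex",
    "validate_nhs_number",
    "clean_hospital_number",
    "clean_date",
    "clean_record",
    "clean_frame",
    "reference_forenames",
]

_NON_ALPHA = re.compile(r"[^A-Z]")
_WS = re.compile(r"\s+")
_PREFIXED_HOSPITAL = re.compile(r"^([A-Z0-9]+):(\d+)$")

DEFAULT_PLACEHOLDER_FORENAMES = ("BABY", "INFANT", "TWIN", "TRIPLET", "UNNAMED", "UNKNOWN")
DEFAULT_SEX_SYNONYMS = {"MALE": "M", "FEMALE": "F", "UNKNOWN": "U", "UNK": "U", "NOTKNOWN": "U"}
DEFAULT_TEST_PATIENT_NAMES = ("ZZTEST", "XXTEST", "TESTPATIENT", "DONOTUSE")
DEFAULT_SUPPRESSED_CLINICS = ("GUM", "GENITOURINARY", "OCCH", "OCCUPATIONALHEALTH")
# NHS numbers that pass the check digit but are known placeholders
DEFAULT_NHS_BLACKLIST = frozenset(str(d) * 10 for d in range(10))

_NHS_WEIGHTS = (10, 9, 8, 7, 6, 5, 4, 3, 2)


@dataclass(frozen=True)
class CleaningConfig:
    """Tunable cleaning policy with defaults suitable for UK hospital data."""

    date_floor: dt.date = dt.date(1860, 1, 1)
    date_formats: tuple[str, ...] = ("%d%m%Y", "%Y-%m-%d", "%d/%m/%Y")
    placeholder_forenames: tuple[str, ...] = DEFAULT_PLACEHOLDER_FORENAMES
    sex_synonyms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SEX_SYNONYMS))
    nhs_blacklist: frozenset[str] = DEFAULT_NHS_BLACKLIST
    hospital_number_range: tuple[int, int] = (1, 10_000_000)
    strip_hospital_check_digit: bool = False
    suppressed_clinics: tuple[str, ...] = DEFAULT_SUPPRESSED_CLINICS
    test_patient_names: tuple[str, ...] = DEFAULT_TEST_PATIENT_NAMES
    today: Optional[dt.date] = None  # overridable for reproducible tests

    def _today(self) -> dt.date:
        return self.today if self.today is not None else dt.date.today()


@dataclass
class RawRecord:
    """One uncleaned input row; every field except record_id may be absent."""

    record_id: object
    source: Optional[str] = None
    surname: Optional[str] = None
    forename: Optional[str] = None
    sex: Optional[str] = None
    birthdate: Optional[str] = None
    deathdate: Optional[str] = None
    nhs_number: Optional[str] = None
    hospital_number: Optional[str] = None
    hospital_code: Optional[str] = None
    clinic_code: Optional[str] = None


@dataclass
class CleanRecord:
    """Validated identifier tuple; ``suppressed`` marks policy-nulled records."""

    record_id: object
    source: Optional[str] = None
    surname: Optional[str] = None
    forename: Optional[str] = None
    sex: Optional[str] = None
    birthdate: Optional[str] = None  # ISO YYYY-MM-DD
    deathdate: Optional[str] = None
    nhs_number: Optional[str] = None
    hospital_number: Optional[str] = None
    suppressed: bool = False


def _is_null(value) -> bool:
    return value is None or value != value or (isinstance(value, str) and not value.strip())


def clean_name(
    value,
    *,
    is_forename: bool = False,
    placeholder_tokens: Iterable[str] = DEFAULT_PLACEHOLDER_FORENAMES,
) -> Optional[str]:
    """Uppercase, strip everything outside A-Z, and null degenerate names.

    A result shorter than two letters is nulled, as is a forename containing a
    configured placeholder token (``BABY OF SMITH`` and friends).
    """
    if _is_null(value):
        return None
    cleaned = _NON_ALPHA.sub("", str(value).upper())
    if len(cleaned) < 2:
        return None
    if is_forename and any(tok in cleaned for tok in placeholder_tokens):
        return None
    return cleaned


def maybe_swap_names(forename, surname, reference_forenames: set) -> tuple:
    """Reverse the name pair when the stated forename is unknown but the surname is a known forename."""
    if _is_null(forename) or _is_null(surname):
        return forename, surname
    if forename not in reference_forenames and surname in reference_forenames:
        return surname, forename
    return forename, surname


def clean_sex(value, synonyms: Optional[dict] = None) -> Optional[str]:
    """Normalise to M / F / U via a synonym table, else the leading character, else null."""
    if _is_null(value):
        return None
    token = _WS.sub("", str(value).upper())
    table = DEFAULT_SEX_SYNONYMS if synonyms is None else synonyms
    if token in table:
        return table[token]
    if token and token[0] in ("M", "F", "U"):
        return token[0]
    return None


def validate_nhs_number(value, blacklist: frozenset = DEFAULT_NHS_BLACKLIST) -> Optional[str]:
    """Return the 10-digit NHS number when it passes the Modulus-11 check, else None.

    Digits 1-9 are weighted 10..2; the check digit is ``11 - (sum mod 11)``,
    with 11 mapped to 0 and 10 marking the number as invalid (never issued).
    """
    if _is_null(value):
        return None
    digits = _WS.sub("", str(value)).replace("-", "")
    if len(digits) != 10 or not digits.isdigit():
        return None
    if digits in blacklist:
        return None
    total = sum(int(d) * w for d, w in zip(digits[:9], _NHS_WEIGHTS))
    check = 11 - total % 11
    if check == 11:
        check = 0
    if check == 10 or check != int(digits[9]):
        return None
    return digits


def clean_hospital_number(
    value,
    hospital_code=None,
    valid_range: tuple[int, int] = (1, 10_000_000),
    strip_check_digit: bool = False,
) -> Optional[str]:
    """Normalise a hospital number, range-check it, and prefix the issuing hospital's code.

    Prefixing (``123456`` from hospital A -> ``A:123456``) guarantees
    cross-hospital uniqueness when several hospitals issue numbers
    independently. Already-prefixed values are accepted unchanged so that
    cleaning is idempotent.
    """
    if _is_null(value):
        return None
    token = _WS.sub("", str(value)).upper()
    m = _PREFIXED_HOSPITAL.match(token)
    if m:  # already carries a hospital prefix
        prefix, digits = m.group(1), m.group(2)
    else:
        prefix, digits = None, token
    if strip_check_digit and len(digits) > 1:
        digits = digits[:-1]
    if not digits.isdigit():
        return None
    lo, hi = valid_range
    if not lo <= int(digits) <= hi:
        return None
    if prefix is not None:
        return f"{prefix}:{digits}"
    if not _is_null(hospital_code):
        code = _WS.sub("", str(hospital_code)).upper()
        return f"{code}:{digits}"
    return digits


def clean_date(
    value,
    floor: dt.date = dt.date(1860, 1, 1),
    formats: tuple[str, ...] = ("%d%m%Y", "%Y-%m-%d", "%d/%m/%Y"),
    today: Optional[dt.date] = None,
) -> Optional[str]:
    """Parse a date per the configured formats; null when unparseable, pre-floor, or future.

    Returns ISO ``YYYY-MM-DD`` so cleaned frames round-trip through CSV.
    """
    if _is_null(value):
        return None
    if isinstance(value, dt.datetime):
        parsed = value.date()
    elif isinstance(value, dt.date):
        parsed = value
    else:
        token = str(value).strip()
        parsed = None
        for fmt in formats:
            try:
                parsed = dt.datetime.strptime(token, fmt).date()
                break
            except ValueError:
                continue
        if parsed is None:
            return None
    if parsed < floor or parsed > (today if today is not None else dt.date.today()):
        return None
    return parsed.isoformat()


def clean_record(
    raw,
    config: Optional[CleaningConfig] = None,
    reference_forenames: Optional[set] = None,
) -> CleanRecord:
    """Apply all field-level cleaners to one raw record.

    ``raw`` may be a RawRecord, a dict, or anything with the raw field names as
    attributes. Suppressed-clinic records and internal test patients are nulled
    per policy after field cleaning.
    """
    cfg = config or CleaningConfig()
    if isinstance(raw, dict):
        raw = RawRecord(**{f.name: raw.get(f.name) for f in dc_fields(RawRecord)})

    clinic = None if _is_null(raw.clinic_code) else _WS.sub("", str(raw.clinic_code)).upper()
    if clinic in cfg.suppressed_clinics:
        return CleanRecord(record_id=raw.record_id, source=raw.source, suppressed=True)

    surname = clean_name(raw.surname, placeholder_tokens=cfg.placeholder_forenames)
    forename = clean_name(raw.forename, is_forename=True, placeholder_tokens=cfg.placeholder_forenames)
    if surname in cfg.test_patient_names or forename in cfg.test_patient_names:
        surname = forename = None
    if reference_forenames:
        forename, surname = maybe_swap_names(forename, surname, reference_forenames)

    return CleanRecord(
        record_id=raw.record_id,
        source=raw.source,
        surname=surname,
        forename=forename,
        sex=clean_sex(raw.sex, cfg.sex_synonyms),
        birthdate=clean_date(raw.birthdate, cfg.date_floor, cfg.date_formats, cfg._today()),
        deathdate=clean_date(raw.deathdate, cfg.date_floor, cfg.date_formats, cfg._today()),
        nhs_number=validate_nhs_number(raw.nhs_number, cfg.nhs_blacklist),
        hospital_number=clean_hospital_number(
            raw.hospital_number,
            raw.hospital_code,
            cfg.hospital_number_range,
            cfg.strip_hospital_check_digit,
        ),
    )


_CLEAN_COLUMNS = [f.name for f in dc_fields(CleanRecord)]
_AUDITED_FIELDS = (
    "surname",
    "forename",
    "sex",
    "birthdate",
    "deathdate",
    "nhs_number",
    "hospital_number",
)


def clean_frame(
    records: pd.DataFrame,
    config: Optional[CleaningConfig] = None,
    reference_forenames: Optional[set] = None,
    with_audit: bool = False,
):
    """Clean every row of a raw-record frame, preserving record_id order.

    Returns the cleaned frame, or ``(cleaned, audit)`` when ``with_audit`` is
    set; the audit lists one row per (record_id, field) whose raw value was
    nulled, changed, or suppressed.
    """
    cfg = config or CleaningConfig()
    raw_fields = [f.name for f in dc_fields(RawRecord)]
    rows = []
    audit: list[dict] = []
    for raw in records.to_dict("records"):
        rec = RawRecord(**{k: raw.get(k) for k in raw_fields})
        cleaned = clean_record(rec, cfg, reference_forenames)
        rows.append(vars(cleaned).copy())
        if with_audit:
            for fname in _AUDITED_FIELDS:
                before, after = getattr(rec, fname), getattr(cleaned, fname)
                if _is_null(before):
                    continue
                if after is None:
                    action = "suppressed" if cleaned.suppressed else "nulled"
                    audit.append(
                        {"record_id": rec.record_id, "field": fname, "raw": before, "action": action}
                    )
                elif str(before) != str(after):
                    audit.append(
                        {"record_id": rec.record_id, "field": fname, "raw": before, "action": "normalised"}
                    )
    out = pd.DataFrame(rows, columns=_CLEAN_COLUMNS)
    if with_audit:
        return out, pd.DataFrame(audit, columns=["record_id", "field", "raw", "action"])
    return out


def reference_forenames(
    records: pd.DataFrame,
    sources: Optional[tuple[str, ...]] = None,
    min_count: int = 2,
) -> set:
    """Build the known-forename set used by the name-swap rule.

    Drawn from the dataset's own forename column (optionally restricted to the
    best-curated sources, e.g. the patient administration system), keeping
    forenames seen at least ``min_count`` times.
    """
    frame = records
    if sources is not None and "source" in frame.columns:
        frame = frame[frame["source"].isin(sources)]
    counts: dict[str, int] = {}
    for value in frame.get("forename", pd.Series(dtype=object)):
        name = clean_name(value, is_forename=True)
        if name is not None:
            counts[name] = counts.get(name, 0) + 1
    return {name for name, c in counts.items() if c >= min_count}
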