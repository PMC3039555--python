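"""Constructed high-cardinality identifiers.

Surname + first three forename letters + date of birth has cardinality
comparable to a purpose-built unique identifier, which makes it usable as a
third exact-match key alongside NHS and hospital numbers. The cardinality
report quantifies that: for each candidate identifier it counts distinct
values and the mean number of distinct reference identifiers (typically NHS
numbers) mapping to each value — a mean near 1 marks a near-unique key.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import pandas as pd

__all__ = ["build_composite", "add_composite", "cardinality_report"]

SEPARATOR = "|"  # cleaning strips all symbols from names, so '|' cannot collide


def _is_null(value) -> bool:
    return value is None or value != value or (isinstance(value, str) and not value)


def build_composite(surname, forename, birthdate) -> Optional[str]:
    """``SURNAME|FFF|YYYY-MM-DD``; None when any component is missing.

    The forename contributes its first three letters (all of them when the
    cleaned forename has only two — cleaning guarantees at least two).
    """
    if _is_null(surname) or _is_null(forename) or _is_null(birthdate):
        return None
    return f"{surname}{SEPARATOR}{str(forename)[:3]}{SEPARATOR}{birthdate}"


def add_composite(records: pd.DataFrame, column: str = "composite_id") -> pd.DataFrame:
    """Return a copy of a cleaned frame with the composite identifier column added."""
    out = records.copy()
    out[column] = [
        build_composite(s, f, b)
        for s, f, b in zip(out["surname"], out["forename"], out["birthdate"])
    ]
    return out


def cardinality_report(
    records: pd.DataFrame,
    candidate_fields: dict[str, Union[str, Sequence[str]]],
    reference_field: str = "nhs_number",
) -> pd.DataFrame:
    """Distinct-value counts and mean reference identifiers per value, per candidate.

    ``candidate_fields`` maps a display name to a column or list of columns
    (a list is treated as a concatenated identifier, null when any part is
    null). Only records with a non-null reference identifier are counted, so
    the mean is >= 1 whenever the report is non-empty.
    """
    rows = []
    mask = ~records[reference_field].map(_is_null).astype(bool)
    frame = records[mask]
    for name, cols in candidate_fields.items():
        if isinstance(cols, str):
            cols = [cols]
        values = []
        for parts in zip(*(frame[c] for c in cols)):
            values.append(None if any(_is_null(p) for p in parts) else SEPARATOR.join(map(str, parts)))
        sub = pd.DataFrame({"value": values, "ref": frame[reference_field].to_numpy()})
        sub = sub[sub["value"].notna()]
        if sub.empty:
            rows.append({"identifier_name": name, "cardinality": 0, "mean_reference_ids_per_value": float("nan")})
            continue
        per_value = sub.groupby("value")["ref"].nunique()
        rows.append(
            {
                "identifier_name": name,
                "cardinality": int(per_value.size),
                "mean_reference_ids_per_value": float(per_value.mean()),
            }
        )
    return pd.DataFrame(rows, columns=["identifier_name", "cardinality", "mean_reference_ids_per_value"])
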