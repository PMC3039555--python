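"""Trigram near-duplicate search across clusters.

Exact-match linkage cannot join records that share no identifier verbatim; the
trigram index finds records *similar* to a query for sensitivity auditing.
Every indexed field value contributes its consecutive 3-character substrings
(values shorter than 3 characters contribute themselves as one token), and
candidates are ranked by the number of distinct shared trigrams pooled across
fields. The output is a candidate list for human review — no automatic merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = ["TrigramIndex", "trigrams", "build_index", "query_top_k", "exact_name_candidates"]

DEFAULT_INDEX_FIELDS = ("surname", "forename", "birthdate", "hospital_number", "nhs_number")


def _null(v) -> bool:
    return v is None or v != v or v == ""


def _dob_token(value) -> Optional[str]:
    """Dates are indexed in ddmmyyyy form (the native wire format of the data)."""
    if _null(value):
        return None
    s = str(value)
    if "-" in s:
        y, m, d = s.split("-")
        return f"{d}{m}{y}"
    return s


def trigrams(value: str) -> set[str]:
    """Distinct consecutive 3-character substrings; the whole value when shorter."""
    s = str(value)
    if len(s) < 3:
        return {s}
    return {s[i : i + 3] for i in range(len(s) - 2)}


@dataclass
class TrigramIndex:
    postings: dict[str, set] = field(default_factory=dict)
    fields_indexed: tuple = DEFAULT_INDEX_FIELDS
    indexed_ids: set = field(default_factory=set)


def _record_trigrams(record: dict, fields: Sequence[str]) -> set[str]:
    grams: set[str] = set()
    for f in fields:
        v = _dob_token(record.get(f)) if f == "birthdate" else record.get(f)
        if not _null(v):
            grams |= trigrams(v)
    return grams


def build_index(
    records: pd.DataFrame,
    fields: Sequence[str] = DEFAULT_INDEX_FIELDS,
) -> TrigramIndex:
    """Index every non-null value of the configured fields of every record."""
    index = TrigramIndex(fields_indexed=tuple(fields))
    for rec in records.to_dict("records"):
        rid = rec["record_id"]
        index.indexed_ids.add(rid)
        for gram in _record_trigrams(rec, fields):
            index.postings.setdefault(gram, set()).add(rid)
    return index


def query_top_k(
    index: TrigramIndex,
    query_record,
    k: int = 10,
) -> list[tuple[object, int]]:
    """Top-k records by distinct shared-trigram count, descending.

    Ties order by ascending record_id; the query's own record (matched by
    record_id) is excluded. ``query_record`` is a dict / Series with the
    indexed field names.
    """
    if isinstance(query_record, pd.Series):
        query_record = query_record.to_dict()
    counts: dict = {}
    for gram in _record_trigrams(query_record, index.fields_indexed):
        for rid in index.postings.get(gram, ()):
            counts[rid] = counts.get(rid, 0) + 1
    own = query_record.get("record_id")
    ranked = sorted(
        ((rid, c) for rid, c in counts.items() if rid != own),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:k]


def exact_name_candidates(records: pd.DataFrame, query_record) -> set:
    """Record ids with cleaned surname and forename both identical to the query's."""
    if isinstance(query_record, pd.Series):
        query_record = query_record.to_dict()
    surname, forename = query_record.get("surname"), query_record.get("forename")
    if _null(surname) or _null(forename):
        return set()
    mask = (records["surname"] == surname) & (records["forename"] == forename)
    return set(records.loc[mask, "record_id"])
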