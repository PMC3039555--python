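"""Exact-match record linkage by iterated set union.

Records sharing any non-null value of any linkage identifier belong to the
same person-cluster; a cluster is a connected component of the graph whose
vertices are records and whose edges are shared identifier values. The join is
implemented as min-label propagation: each sweep replaces every record's
cluster id with the minimum id among records sharing a value, one identifier
field at a time, and repeats until a fixed point. Each sweep is O(m n) for m
identifier fields and n records, and the fixed point is the connected-component
partition regardless of record or field order.

Cluster ids are the minimum *start id* among members (start ids default to the
integer record_id, or the 1-based input position), which makes output ids
deterministic and stable under merges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Cluster",
    "LinkageResult",
    "single_pass_join",
    "link",
    "incremental_add",
    "sharing_edges",
    "DEFAULT_IDENTIFIER_FIELDS",
]

DEFAULT_IDENTIFIER_FIELDS = ("nhs_number", "hospital_number", "composite_id")

_INT_MAX = np.iinfo(np.int64).max


@dataclass
class Cluster:
    """A set of records assigned to one putative individual."""

    cluster_id: int
    records: pd.DataFrame

    @property
    def members(self) -> list:
        return list(self.records["record_id"])

    def values(self, field: str) -> set:
        """Distinct non-null values of one identifier field within the cluster."""
        return {v for v in self.records[field] if v is not None and v == v}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class LinkageResult:
    """Partition of the record set plus the bookkeeping to extend or refine it."""

    assignment: pd.Series  # record_id -> cluster_id
    records: pd.DataFrame  # linked records, input order
    excluded: pd.DataFrame  # records with no valid identifier at all
    start_ids: pd.Series  # record_id -> start cluster id
    identifier_fields: tuple
    iterations: int
    n: int
    m: int

    def clusters(self) -> list[Cluster]:
        """Clusters in ascending cluster-id order."""
        frame = self.records
        cids = self.assignment.loc[frame["record_id"]].to_numpy()
        out = [
            Cluster(int(cid), sub.drop(columns="_cid"))
            for cid, sub in frame.assign(_cid=cids).groupby("_cid", sort=True)
        ]
        return out

    def cluster_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


def _start_ids(records: pd.DataFrame, start_ids) -> np.ndarray:
    if start_ids is not None:
        return np.asarray(start_ids, dtype=np.int64)
    rid = records["record_id"]
    if pd.api.types.is_integer_dtype(rid):
        return rid.to_numpy(dtype=np.int64)
    return np.arange(1, len(records) + 1, dtype=np.int64)


def _field_codes(records: pd.DataFrame, fields: Sequence[str]):
    """Factorise each identifier column; nulls (None/NaN/empty) code to -1."""
    coded = []
    for f in fields:
        if f not in records.columns:
            raise KeyError(f"unknown identifier field {f!r}; available: {list(records.columns)}")
        col = records[f].to_numpy(dtype=object)
        col = np.array([None if v is None or v != v or v == "" else v for v in col], dtype=object)
        codes, uniques = pd.factorize(col)
        coded.append((codes, len(uniques)))
    return coded


def _group_min_pass(codes: np.ndarray, n_values: int, cid: np.ndarray) -> np.ndarray:
    """One hash-join pass on one field: every record takes the minimum cluster
    id among records sharing its value."""
    if n_values == 0:
        return cid
    valid = codes >= 0
    gmin = np.full(n_values, _INT_MAX, dtype=np.int64)
    np.minimum.at(gmin, codes[valid], cid[valid])
    out = cid.copy()
    out[valid] = np.minimum(cid[valid], gmin[codes[valid]])
    return out


def _split_unidentified(records: pd.DataFrame, fields: Sequence[str]):
    mask = np.ones(len(records), dtype=bool)
    for f in fields:
        col = records[f].to_numpy(dtype=object)
        nonnull = np.array([v is not None and v == v and v != "" for v in col])
        mask &= ~nonnull
    return records[~mask].reset_index(drop=True), records[mask].reset_index(drop=True)


def single_pass_join(
    records: pd.DataFrame,
    identifier_field: str,
    start_ids=None,
) -> LinkageResult:
    """A single set-union join on one identifier field.

    Merged groups adopt the minimum incoming cluster id; records whose value is
    null (or unshared) keep their start id. This is one step of the iterative
    procedure that :func:`link` runs to its fixed point.
    """
    records = records.reset_index(drop=True)
    sid = _start_ids(records, start_ids)
    (codes, n_values), = _field_codes(records, [identifier_field])
    cid = _group_min_pass(codes, n_values, sid.copy())
    assignment = pd.Series(cid, index=pd.Index(records["record_id"], name="record_id"), name="cluster_id")
    return LinkageResult(
        assignment=assignment,
        records=records,
        excluded=records.iloc[0:0],
        start_ids=pd.Series(sid, index=assignment.index, name="start_id"),
        identifier_fields=(identifier_field,),
        iterations=1,
        n=len(records),
        m=1,
    )


def link(
    records: pd.DataFrame,
    identifier_fields: Sequence[str] = DEFAULT_IDENTIFIER_FIELDS,
    start_ids=None,
    dedupe: bool = False,
    exclude_unidentified: bool = True,
) -> LinkageResult:
    """Cluster records sharing any non-null identifier value, transitively.

    Iterates :func:`single_pass_join` over every field until no id changes; the
    result equals connected components of the identifier-sharing graph and is
    independent of record and field order. Records carrying no valid identifier
    at all cannot be linked and are reported separately in ``excluded``.

    ``dedupe=True`` first collapses rows with identical identifier tuples (the
    natural unit of linkage when the same combination recurs many times) and
    then broadcasts the partition back to all rows; the partition is identical
    either way.
    """
    if not len(identifier_fields):
        raise ValueError("identifier_fields must be non-empty")
    records = records.reset_index(drop=True)
    all_sids = _start_ids(records, start_ids)
    sid_by_record = pd.Series(all_sids, index=pd.Index(records["record_id"], name="record_id"))
    if exclude_unidentified:
        kept, excluded = _split_unidentified(records, identifier_fields)
    else:
        kept, excluded = records, records.iloc[0:0]
    sid = sid_by_record.loc[kept["record_id"]].to_numpy()

    if dedupe and len(kept):
        key_codes = [pd.factorize(kept[f].to_numpy(dtype=object))[0] for f in identifier_fields]
        combo, _ = pd.factorize(pd.MultiIndex.from_arrays(key_codes))
        reps = pd.Series(np.arange(len(kept))).groupby(combo).min().to_numpy()
        rep_frame = kept.iloc[reps].reset_index(drop=True)
        rep_sid = pd.Series(sid).groupby(combo).min().to_numpy()
        sub = link(rep_frame, identifier_fields, start_ids=rep_sid, dedupe=False,
                   exclude_unidentified=False)
        rep_cid = sub.assignment.to_numpy()
        cid = rep_cid[combo]
        # merged groups adopt the min start id over *all* rows they contain
        final = pd.Series(sid).groupby(cid).min()
        cid = final.loc[cid].to_numpy()
        iterations = sub.iterations
    else:
        coded = _field_codes(kept, identifier_fields)
        cid = sid.copy()
        iterations = 0
        while True:
            iterations += 1
            before = cid
            for codes, n_values in coded:
                cid = _group_min_pass(codes, n_values, cid)
            if np.array_equal(before, cid):
                break

    assignment = pd.Series(
        cid, index=pd.Index(kept["record_id"], name="record_id"), name="cluster_id", dtype=np.int64
    )
    if assignment.index.has_duplicates:
        raise ValueError("duplicate record_id values in input")
    return LinkageResult(
        assignment=assignment,
        records=kept,
        excluded=excluded,
        start_ids=sid_by_record.rename("start_id"),
        identifier_fields=tuple(identifier_fields),
        iterations=max(iterations, 1),
        n=len(kept),
        m=len(identifier_fields),
    )


def incremental_add(result: LinkageResult, new_records: pd.DataFrame) -> LinkageResult:
    """Extend an existing linkage with new records.

    Equivalent by contract to re-linking the union; new records receive start
    ids continuing after the existing maximum unless their record_id column is
    already integer-typed.
    """
    new_records = new_records.reset_index(drop=True)
    existing = set(result.start_ids.index)
    dup = [r for r in new_records["record_id"] if r in existing]
    if dup:
        raise ValueError(f"duplicate record_id values: {dup[:5]}")
    combined = pd.concat([result.records, result.excluded, new_records], ignore_index=True)
    if pd.api.types.is_integer_dtype(combined["record_id"]):
        sids = None
    else:
        old = result.start_ids
        nxt = int(old.max()) + 1 if len(old) else 1
        new_sids = pd.Series(
            np.arange(nxt, nxt + len(new_records), dtype=np.int64),
            index=pd.Index(new_records["record_id"], name="record_id"),
        )
        sids = pd.concat([old, new_sids]).loc[combined["record_id"]].to_numpy()
    return link(combined, result.identifier_fields, start_ids=sids)


def sharing_edges(records: pd.DataFrame, identifier_fields: Sequence[str]) -> pd.DataFrame:
    """Explicit edge list of the identifier-sharing graph, for export or plotting.

    One row per record pair per shared value; quadratic in the size of a value
    group, so intended for inspection of modest datasets, not bulk linkage.
    """
    rows = []
    rid = records["record_id"].to_numpy(dtype=object)
    for f in identifier_fields:
        by_value: dict = {}
        for i, v in enumerate(records[f].to_numpy(dtype=object)):
            if v is None or v != v or v == "":
                continue
            by_value.setdefault(v, []).append(i)
        for v, idx in by_value.items():
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    rows.append(
                        {"record_a": rid[idx[a]], "record_b": rid[idx[b]], "field": f, "value": v}
                    )
    return pd.DataFrame(rows, columns=["record_a", "record_b", "field", "value"])
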