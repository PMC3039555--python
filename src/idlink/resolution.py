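"""Resolution of identity collisions by single-identifier deletion.

The working hypothesis: a bad cluster is two single-person clusters welded by
one erroneous identifier instance. Viewing shared identifiers as graph edges,
the erroneous identifier is an edge origin, so deleting the right single
instance disconnects the cluster. Candidate instances are exactly the
(record, field, value) triples whose value is shared with another record of
the cluster; each candidate variant is re-clustered, and the variant that
divides the cluster while maximising the gain in *invariant* identifiers
(linkage fields whose within-part cardinality is exactly 1) wins, with a
seeded uniform tie-break.

``resolve_all`` applies this over a whole linkage: complex clusters are scored
with the logistic classifier, flagged clusters are split, and the resulting
partition — always a refinement of the input — is re-scored once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection import LogisticModel, extract_features, is_complex, published_models, score_cluster
from .linkage import DEFAULT_IDENTIFIER_FIELDS, Cluster, LinkageResult

__all__ = [
    "SplitCandidate",
    "SplitOutcome",
    "ResolutionReport",
    "candidate_identifiers",
    "split_cluster",
    "resolve_all",
]


@dataclass(frozen=True)
class SplitCandidate:
    """One identifier instance (a single field of a single record) that forms edges."""

    record_id: object
    field: str
    value: object


@dataclass
class SplitOutcome:
    """Result of attempting to split one cluster."""

    deleted: Optional[SplitCandidate]
    clusters: list[Cluster]
    quality_gain: int
    tie_count: int = 0
    n_parts: int = 1


@dataclass
class ResolutionReport:
    n_clusters_in: int
    n_complex: int
    n_flagged_bad: int
    n_splits: int
    n_clusters_out: int
    n_bad_after_rescore: int
    splits: pd.DataFrame  # one row per attempted split


def _null(v) -> bool:
    return v is None or v != v or v == ""


def _rows_of(cluster: Cluster, fields: Sequence[str]) -> list[dict]:
    cols = ["record_id", *fields]
    return cluster.records[cols].to_dict("records")


def _component_labels(rows: list[dict], fields: Sequence[str]) -> list[int]:
    """Union-find connected components of the identifier-sharing graph on a
    handful of rows; pure-python because this sits in the splitting hot loop."""
    parent = list(range(len(rows)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for f in fields:
        first: dict = {}
        for i, r in enumerate(rows):
            v = r[f]
            if _null(v):
                continue
            if v in first:
                ra, rb = find(first[v]), find(i)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
            else:
                first[v] = i
    return [find(i) for i in range(len(rows))]


def _invariant_count(rows: list[dict], labels: Sequence[int], fields: Sequence[str]) -> int:
    """Number of (part, field) combinations whose non-null value set has cardinality 1."""
    values: dict[tuple, set] = {}
    for r, lab in zip(rows, labels):
        for f in fields:
            v = r[f]
            if not _null(v):
                values.setdefault((lab, f), set()).add(v)
    return sum(1 for s in values.values() if len(s) == 1)


def candidate_identifiers(
    cluster: Cluster,
    identifier_fields: Sequence[str] = DEFAULT_IDENTIFIER_FIELDS,
) -> list[SplitCandidate]:
    """All identifier instances whose value is shared by >= 2 records of the cluster.

    Only shared values form edges, so only these instances can disconnect the
    cluster when deleted; enumeration order is deterministic (field order, then
    record order).
    """
    rows = _rows_of(cluster, identifier_fields)
    out: list[SplitCandidate] = []
    for f in identifier_fields:
        counts: dict = {}
        for r in rows:
            v = r[f]
            if not _null(v):
                counts[v] = counts.get(v, 0) + 1
        for r in rows:
            v = r[f]
            if not _null(v) and counts[v] >= 2:
                out.append(SplitCandidate(r["record_id"], f, v))
    return out


def split_cluster(
    cluster: Cluster,
    identifier_fields: Sequence[str] = DEFAULT_IDENTIFIER_FIELDS,
    rng_seed=0,
    value_level: bool = False,
) -> SplitOutcome:
    """Try every one-identifier-deletion variant and keep the best division.

    A variant nulls a single candidate instance (or, with ``value_level``,
    every instance of the candidate's value), re-clusters the remaining
    records, and measures ``quality_gain``: the increase in invariant
    identifier fields summed over the resulting parts. The winning variant
    must both divide the cluster and achieve a strictly positive gain;
    otherwise no split is performed. Ties are broken uniformly at random with
    the given seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    rows = _rows_of(cluster, identifier_fields)
    whole = [0] * len(rows)
    base = _invariant_count(rows, whole, identifier_fields)

    best_gain = 0
    best: list[tuple[SplitCandidate, list[int], int]] = []
    for cand in candidate_identifiers(cluster, identifier_fields):
        saved = []
        for i, r in enumerate(rows):
            if r[cand.field] == cand.value and (value_level or r["record_id"] == cand.record_id):
                saved.append((i, r[cand.field]))
                r[cand.field] = None
        labels = _component_labels(rows, identifier_fields)
        n_parts = len(set(labels))
        gain = _invariant_count(rows, labels, identifier_fields) - base
        for i, v in saved:
            rows[i][cand.field] = v
        if n_parts < 2 or gain <= 0:
            continue
        if gain > best_gain:
            best_gain, best = gain, [(cand, labels, n_parts)]
        elif gain == best_gain:
            best.append((cand, labels, n_parts))

    if not best:
        return SplitOutcome(None, [cluster], 0, tie_count=0, n_parts=1)

    cand, labels, n_parts = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
    records = cluster.records.copy()
    mask = records["record_id"] == cand.record_id if not value_level else records[cand.field] == cand.value
    records.loc[mask & (records[cand.field] == cand.value), cand.field] = None
    parts = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        sub = records.iloc[idx].reset_index(drop=True)
        parts.append(Cluster(cluster.cluster_id, sub))  # ids reassigned by resolve_all
    return SplitOutcome(cand, parts, best_gain, tie_count=len(best), n_parts=n_parts)


def resolve_all(
    linkage: LinkageResult,
    models: Optional[tuple[LogisticModel, LogisticModel]] = None,
    rng_seed=0,
    value_level: bool = False,
) -> tuple[LinkageResult, ResolutionReport]:
    """Score every complex cluster, split the ones flagged bad, re-score once.

    Returns the refined linkage (cluster ids re-derived as the minimum member
    start id) and a report with per-split details. Deletion-only splitting
    guarantees the output partition refines the input and conserves records.
    """
    if models is None:
        models = published_models()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    fields = linkage.identifier_fields

    out_clusters: list[Cluster] = []
    split_rows: list[dict] = []
    n_complex = n_bad = n_splits = 0
    for cluster in linkage.clusters():
        if len(cluster) < 2 or not is_complex(cluster, fields):
            out_clusters.append(cluster)
            continue
        n_complex += 1
        score, label = score_cluster(extract_features(cluster), models)
        if label != "bad":
            out_clusters.append(cluster)
            continue
        n_bad += 1
        outcome = split_cluster(cluster, fields, rng, value_level=value_level)
        out_clusters.extend(outcome.clusters)
        if outcome.deleted is not None:
            n_splits += 1
        split_rows.append(
            {
                "cluster_id": cluster.cluster_id,
                "score": score,
                "deleted_record_id": outcome.deleted.record_id if outcome.deleted else None,
                "deleted_field": outcome.deleted.field if outcome.deleted else None,
                "deleted_value": outcome.deleted.value if outcome.deleted else None,
                "n_parts": outcome.n_parts,
                "quality_gain": outcome.quality_gain,
                "tie_count": outcome.tie_count,
            }
        )

    # rebuild the partition with min-start-id cluster ids
    start = linkage.start_ids
    pieces = []
    for c in out_clusters:
        cid = int(start.loc[c.records["record_id"]].min())
        pieces.append((cid, Cluster(cid, c.records)))
    pieces.sort(key=lambda t: t[0])
    assignment = pd.concat(
        [
            pd.Series(cid, index=pd.Index(c.records["record_id"], name="record_id"))
            for cid, c in pieces
        ]
    ).rename("cluster_id")
    records = pd.concat([c.records for _, c in pieces], ignore_index=True)
    resolved = LinkageResult(
        assignment=assignment,
        records=records,
        excluded=linkage.excluded,
        start_ids=linkage.start_ids,
        identifier_fields=fields,
        iterations=linkage.iterations,
        n=linkage.n,
        m=linkage.m,
    )

    n_bad_after = 0
    for _, c in pieces:
        if len(c) < 2 or not is_complex(c, fields):
            continue
        _, label = score_cluster(extract_features(c), models)
        if label == "bad":
            n_bad_after += 1

    report = ResolutionReport(
        n_clusters_in=len(linkage.clusters()),
        n_complex=n_complex,
        n_flagged_bad=n_bad,
        n_splits=n_splits,
        n_clusters_out=len(pieces),
        n_bad_after_rescore=n_bad_after,
        splits=pd.DataFrame(
            split_rows,
            columns=[
                "cluster_id",
                "score",
                "deleted_record_id",
                "deleted_field",
                "deleted_value",
                "n_parts",
                "quality_gain",
                "tie_count",
            ],
        ),
    )
    return resolved, report
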