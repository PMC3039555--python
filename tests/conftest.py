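import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import idlink as il


@pytest.fixture
def worked():
    """Six clean records, three patients all named David Wilson, start ids 1-6."""
    return il.datasets.worked_example()


@pytest.fixture
def good_clusters():
    return il.make_good_clusters(40, rng_seed=123)


def partition_of(assignment: pd.Series) -> set:
    """Cluster-id-free view of a partition, for order-invariant comparison."""
    groups = {}
    for rid, cid in assignment.items():
        groups.setdefault(cid, set()).add(rid)
    return {frozenset(g) for g in groups.values()}


def brute_force_partition(records: pd.DataFrame, fields) -> set:
    """Independent O(n^2) oracle: connected components of the explicit pairwise
    identifier-sharing relation."""
    g = nx.Graph()
    g.add_nodes_from(records["record_id"])
    rows = records.to_dict("records")
    for a, b in itertools.combinations(rows, 2):
        for f in fields:
            va, vb = a[f], b[f]
            if va is None or va != va or va == "":
                continue
            if va == vb:
                g.add_edge(a["record_id"], b["record_id"])
                break
    return {frozenset(c) for c in nx.connected_components(g)}


def brute_force_partition_fast(records: pd.DataFrame, fields) -> set:
    """Vectorised variant of the same oracle (dense pairwise equality matrix)."""
    n = len(records)
    adj = np.zeros((n, n), dtype=bool)
    for f in fields:
        codes, _ = pd.factorize(records[f])
        valid = codes >= 0
        adj |= (codes[:, None] == codes[None, :]) & valid[:, None] & valid[None, :]
    np.fill_diagonal(adj, False)
    g = nx.from_numpy_array(adj)
    rid = records["record_id"].to_numpy()
    return {frozenset(rid[list(c)]) for c in nx.connected_components(g)}
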