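"""String distance primitives used for intra-cluster feature extraction.

Levenshtein is used on short, fixed-width tokens (date-of-birth components,
single-letter sex codes); Jaro-Winkler on names and hospital numbers. Both are
implemented here directly: the strings involved are tiny, and keeping the
primitives in-package avoids a runtime dependency for two short functions.
"""

from __future__ import annotations


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute) between two strings."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):  # iterate over the longer string row-wise
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def jaro_similarity(a: str, b: str) -> float:
    """Jaro similarity in [0, 1]; 1 for two empty strings, 0 when no characters match."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    match_a = [False] * la
    match_b = [False] * lb
    matches = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = True
                match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # transpositions: matched characters out of order, counted pairwise
    bj = [b[j] for j in range(lb) if match_b[j]]
    transpositions = sum(ca != cb for ca, cb in zip((a[i] for i in range(la) if match_a[i]), bj))
    m = float(matches)
    return (m / la + m / lb + (m - transpositions / 2.0) / m) / 3.0


def jaro_winkler_similarity(a: str, b: str, prefix_scale: float = 0.1, max_prefix: int = 4) -> float:
    """Jaro similarity boosted by a common-prefix bonus (standard scale 0.1, prefix <= 4)."""
    sim = jaro_similarity(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= max_prefix:
            break
        prefix += 1
    return sim + prefix * prefix_scale * (1.0 - sim)


def jaro_winkler_distance(a: str, b: str) -> float:
    """1 - Jaro-Winkler similarity: 0 for identical strings, 1 for fully dissimilar."""
    return 1.0 - jaro_winkler_similarity(a, b)
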