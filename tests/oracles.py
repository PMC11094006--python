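"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: plain dynamic
programming, exhaustive enumeration and naive quantile arithmetic.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def nw_identity_candidates(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> set[float]:
    """Identities (matches / columns) of *all* optimal global alignments."""
    n, m = len(a), len(b)
    s = np.zeros((n + 1, m + 1))
    s[1:, 0] = gap * np.arange(1, n + 1)
    s[0, 1:] = gap * np.arange(1, m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = s[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            s[i, j] = max(diag, s[i - 1, j] + gap, s[i, j - 1] + gap)
    out: set[float] = set()

    def walk(i: int, j: int, ident: int, cols: int) -> None:
        if i == 0 and j == 0:
            out.add(ident / cols)
            return
        if i > 0 and j > 0:
            step = match if a[i - 1] == b[j - 1] else mismatch
            if math.isclose(s[i, j], s[i - 1, j - 1] + step):
                walk(i - 1, j - 1, ident + (a[i - 1] == b[j - 1]), cols + 1)
        if i > 0 and math.isclose(s[i, j], s[i - 1, j] + gap):
            walk(i - 1, j, ident, cols + 1)
        if j > 0 and math.isclose(s[i, j], s[i, j - 1] + gap):
            walk(i, j - 1, ident, cols + 1)

    walk(n, m, 0, 0)
    return out


def single_linkage_partition(
    ids: list[str], identity: dict[tuple[str, str], float], threshold: float
) -> set[frozenset[str]]:
    """Brute-force single-linkage clustering at an identity threshold."""
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for x, y in itertools.combinations(ids, 2):
        ident = identity.get((x, y), identity.get((y, x)))
        if ident is not None and ident >= threshold:
            parent[find(x)] = find(y)
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def tukey_outliers(depths: list[float]) -> set[int]:
    """Naive IQR-fence outlier indices with manual linear-interp quartiles."""
    xs = sorted(depths)
    n = len(xs)

    def quantile(q: float) -> float:
        pos = q * (n - 1)
        lo, hi = int(math.floor(pos)), int(math.ceil(pos))
        if lo == hi:
            return xs[lo]
        frac = pos - lo
        return xs[lo] * (1 - frac) + xs[hi] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {i for i, d in enumerate(depths) if d < lo or d > hi}


def anosim_r(dist: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ANOSIM R computed with naive midrank assignment."""
    n = dist.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    values = [dist[i, j] for i, j in pairs]
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    k = 0
    while k < len(order):
        k2 = k
        while (
            k2 + 1 < len(order)
            and values[order[k2 + 1]] == values[order[k]]
        ):
            k2 += 1
        mid = (k + k2) / 2 + 1
        for idx in order[k : k2 + 1]:
            ranks[idx] = mid
        k = k2 + 1
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2)


def anosim_exhaustive_p(dist: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p over all distinct label assignments."""
    n = dist.shape[0]
    observed = anosim_r(dist, labels)
    uniq = sorted(set(labels))
    assert len(uniq) == 2
    k = int(np.sum(labels == uniq[0]))
    hits = total = 0
    for combo in itertools.combinations(range(n), k):
        lab = np.array([uniq[0] if i in combo else uniq[1] for i in range(n)])
        total += 1
        if anosim_r(dist, lab) >= observed - 1e-12:
            hits += 1
    return hits / total
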