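"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (enumeration, O(n^2) scans, per-element
loops) kept separate from the package code paths they verify.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# peak counting (serration oracle)
# ---------------------------------------------------------------------------


def brute_force_peak_count(profile, threshold: float) -> int:
    """Count local maxima of a 1D profile with prominence >= threshold.

    Plateaus are collapsed to single samples first; prominence of a peak is
    its height minus the higher of the two valley minima found by scanning
    outward to the nearest strictly higher samples (or the ends).
    """
    vals = [profile[0]]
    for v in profile[1:]:
        if v != vals[-1]:
            vals.append(v)
    n = len(vals)
    count = 0
    for i in range(1, n - 1):
        if not (vals[i] > vals[i - 1] and vals[i] > vals[i + 1]):
            continue
        left_min = vals[i]
        j = i - 1
        while j >= 0 and vals[j] < vals[i]:
            left_min = min(left_min, vals[j])
            j -= 1
        right_min = vals[i]
        j = i + 1
        while j < n and vals[j] < vals[i]:
            right_min = min(right_min, vals[j])
            j += 1
        if vals[i] - max(left_min, right_min) >= threshold:
            count += 1
    return count


def radial_serration_count(margin: np.ndarray, center: np.ndarray,
                           threshold: float) -> int:
    """Serration count from the radial profile about a known wing base."""
    r = np.hypot(*(np.asarray(margin) - np.asarray(center)).T)
    return brute_force_peak_count(list(r), threshold)


# ---------------------------------------------------------------------------
# biallelic HWE exact test (closed-form enumeration)
# ---------------------------------------------------------------------------


def biallelic_hwe_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE p-value for two alleles via math.comb only."""
    n = n_aa + n_ab + n_bb
    a = 2 * n_aa + n_ab  # copies of the first allele
    b = 2 * n - a
    if a == 0 or b == 0:
        return 1.0

    def prob(h: int) -> float:
        na = (a - h) // 2
        nb = (b - h) // 2
        num = (math.factorial(n) * 2 ** h * math.factorial(a) * math.factorial(b))
        den = (math.factorial(na) * math.factorial(h) * math.factorial(nb)
               * math.factorial(2 * n))
        return num / den

    p_obs = prob(n_ab)
    total = 0.0
    for h in range(a % 2, min(a, b) + 1, 2):
        p = prob(h)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# exhaustive minimum-evolution tree search (5 leaves)
# ---------------------------------------------------------------------------


def _insert_leaf(edges: list[tuple[int, int]], leaf: int, edge_idx: int,
                 next_node: int) -> list[tuple[int, int]]:
    u, v = edges[edge_idx]
    out = [e for k, e in enumerate(edges) if k != edge_idx]
    out += [(u, next_node), (next_node, v), (next_node, leaf)]
    return out


def enumerate_unrooted_topologies(n_leaves: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies (edge lists) on leaves 0..n-1."""
    trees = [[(0, n_leaves), (1, n_leaves), (2, n_leaves)]]
    next_node = n_leaves + 1
    for leaf in range(3, n_leaves):
        trees = [
            _insert_leaf(t, leaf, k, next_node)
            for t in trees
            for k in range(len(t))
        ]
        next_node += 1
    return trees


def _leaf_paths(edges: list[tuple[int, int]], n_leaves: int):
    """Edge-indicator matrix of leaf-pair paths."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    pairs = list(itertools.combinations(range(n_leaves), 2))
    X = np.zeros((len(pairs), len(edges)))
    for row, (s, t) in enumerate(pairs):
        # DFS path from s to t
        stack = [(s, -1, [])]
        while stack:
            node, parent, path = stack.pop()
            if node == t:
                X[row, path] = 1.0
                break
            for nxt, k in adj[node]:
                if nxt != parent:
                    stack.append((nxt, node, path + [k]))
    return pairs, X


def minimum_evolution_splits(d: np.ndarray) -> set[frozenset]:
    """Best topology by OLS branch lengths + minimum total length; returns
    its internal splits as frozensets of leaf indices (side without leaf 0)."""
    n = d.shape[0]
    best = None
    for edges in enumerate_unrooted_topologies(n):
        pairs, X = _leaf_paths(edges, n)
        y = np.array([d[i, j] for i, j in pairs])
        bl, *_ = np.linalg.lstsq(X, y, rcond=None)
        score = float(np.sum(np.clip(bl, 0, None)))
        resid = float(np.sum((X @ bl - y) ** 2))
        key = (round(resid, 9), score)
        if best is None or key < best[0]:
            best = (key, edges)
    edges = best[1]
    # splits: for each internal edge, the leaf set on one side
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        if u < n or v < n:
            continue  # pendant edge
        # leaves reachable from v without crossing u
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """Random additive distance matrix plus the generating splits."""
    edges = enumerate_unrooted_topologies(n_leaves)[
        rng.integers(len(enumerate_unrooted_topologies(n_leaves)))]
    lengths = rng.uniform(0.5, 2.0, size=len(edges))
    pairs, X = _leaf_paths(edges, n_leaves)
    d = np.zeros((n_leaves, n_leaves))
    for (i, j), row in zip(pairs, X):
        d[i, j] = d[j, i] = float(row @ lengths)
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        if u < n_leaves or v < n_leaves:
            continue
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            if node < n_leaves:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 0 in side:
            side = set(range(n_leaves)) - side
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(frozenset(side))
    return d, splits


# ---------------------------------------------------------------------------
# admixture likelihood (per-copy loop)
# ---------------------------------------------------------------------------


def loop_log_likelihood(geno_idx: np.ndarray, p: np.ndarray,
                        q: np.ndarray) -> float:
    total = 0.0
    n, L, _ = geno_idx.shape
    K = q.shape[1]
    for i in range(n):
        for l in range(L):
            for c in range(2):
                a = geno_idx[i, l, c]
                if a < 0:
                    continue
                mix = sum(q[i, k] * p[k, l, a] for k in range(K))
                if mix <= 0:
                    return float("-inf")
                total += math.log(mix)
    return total
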