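"""Nei's standard genetic distance, neighbor-joining, and locus bootstrap.

For units X, Y (individual plants or whole populations) with per-locus
allele frequencies x, y, Nei's standard distance is
``D = -ln(J_XY / sqrt(J_X J_Y))`` with J the across-locus means of
``sum x_i^2``, ``sum y_i^2`` and ``sum x_i y_i``.  Individuals are treated
as frequency vectors with entries 0, 0.5 or 1.  Trees are built with the
Saitou–Nei neighbor-joining agglomeration; edge supports come from
resampling loci with replacement and counting how often each internal
bipartition of the full-data tree recurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "BootstrapConfig",
    "nei_standard_distance",
    "neighbor_joining",
    "bootstrap_tree",
    "write_newick",
    "read_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if self.d.min() < -1e-12:
            raise ValueError("distances must be non-negative")
        self.d = np.clip(self.d, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class BootstrapConfig:
    """Locus-bootstrap settings (1000 replicates is the field standard)."""

    replicates: int = 1000
    seed: int = 0
    support_display_threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class PhyloTree:
    """Unrooted NJ tree with branch lengths and optional bootstrap supports.

    ``supports`` maps each internal bipartition — canonicalised as the
    frozenset of leaf labels on the side *not* containing the first label —
    to a percentage in [0, 100].
    """

    tree: dendropy.Tree
    labels: list[str]
    supports: dict[frozenset, float] | None = None

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal-edge bipartitions of the tree."""
        out: set[frozenset] = set()
        all_labels = frozenset(self.labels)
        ref = min(self.labels)
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node or node.is_leaf():
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(below) <= len(self.labels) - 2:
                out.add(below if ref not in below else all_labels - below)
        return out

    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Nei distance
# ---------------------------------------------------------------------------


@dataclass
class _NeiParts:
    """Per-locus homozygosity/identity pieces, reusable across bootstraps."""

    labels: list[str]
    sq: np.ndarray      # (U, L): sum of squared frequencies per unit x locus
    cross: np.ndarray   # (U, U, L): sum of cross products per pair x locus
    typed: np.ndarray   # (U, L): unit has frequency data at locus

    def distances(self, locus_idx: np.ndarray | None = None,
                  cap: float | None = None) -> np.ndarray:
        sq, cross, typed = self.sq, self.cross, self.typed
        if locus_idx is not None:
            sq = sq[:, locus_idx]
            cross = cross[:, :, locus_idx]
            typed = typed[:, locus_idx]
        shared = typed[:, None, :] & typed[None, :, :]
        n_shared = shared.sum(axis=2)
        if np.any(n_shared == 0):
            raise ValueError("some unit pairs share no typed locus")
        jx = np.where(shared, sq[:, None, :], 0.0).sum(axis=2) / n_shared
        jy = np.where(shared, sq[None, :, :], 0.0).sum(axis=2) / n_shared
        jxy = np.where(shared, cross, 0.0).sum(axis=2) / n_shared
        with np.errstate(divide="ignore"):
            ratio = jxy / np.sqrt(jx * jy)
            if np.any(ratio <= 0):
                if cap is None:
                    raise ValueError(
                        "units share no alleles (infinite Nei distance); "
                        "pass a finite cap to proceed"
                    )
                d = np.where(ratio > 0, -np.log(np.maximum(ratio, 1e-300)), np.inf)
                d = np.minimum(d, cap)
            else:
                d = -np.log(np.minimum(ratio, 1.0))
        np.fill_diagonal(d, 0.0)
        return (d + d.T) / 2  # exact symmetry


def _frequency_parts(dataset: GenotypeDataset, unit: str) -> _NeiParts:
    if unit == "population":
        labels = list(dataset.populations)
        groups = [dataset.population_members(p) for p in labels]
    elif unit == "individual":
        labels = list(dataset.individuals)
        groups = [np.array([i]) for i in range(dataset.n_individuals)]
    else:
        raise ValueError("unit must be 'population' or 'individual'")

    U, L = len(labels), dataset.n_loci
    sq = np.zeros((U, L))
    cross = np.zeros((U, U, L))
    typed = np.zeros((U, L), dtype=bool)
    for l in range(L):
        col = dataset.calls[:, l, :]
        alleles = np.unique(col[col[:, 0] != MISSING])
        if alleles.size == 0:
            continue
        amap = {int(a): k for k, a in enumerate(alleles)}
        F = np.zeros((U, len(alleles)))
        for u, rows in enumerate(groups):
            sub = col[rows]
            sub = sub[sub[:, 0] != MISSING]
            if len(sub) == 0:
                continue
            typed[u, l] = True
            vals, counts = np.unique(sub.ravel(), return_counts=True)
            for v, c in zip(vals, counts):
                F[u, amap[int(v)]] = c / (2 * len(sub))
        sq[:, l] = np.sum(F * F, axis=1)
        cross[:, :, l] = F @ F.T
    return _NeiParts(labels=labels, sq=sq, cross=cross, typed=typed)


def nei_standard_distance(dataset: GenotypeDataset, unit: str = "individual",
                          cap: float | None = None) -> DistanceMatrix:
    """Nei's standard genetic distance between units (default: individual
    plants, each a 0/0.5/1 frequency vector).

    Means are taken over the loci typed in both units of each pair.  Pairs
    sharing no alleles have infinite D and are rejected unless a finite
    ``cap`` is supplied.
    """
    parts = _frequency_parts(dataset, unit)
    return DistanceMatrix(labels=parts.labels, d=parts.distances(cap=cap))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _nj_merges(d: np.ndarray) -> list[tuple[int, int, float, float]]:
    """Saitou–Nei agglomeration.

    Returns a merge list ``(i, j, len_i, len_j)`` over node ids (leaves are
    ``0..n-1``; each merge creates the next id) ending with a final
    three-way join encoded as two entries sharing the last created id.
    Ties in the Q criterion break to the lexicographically smallest (i, j).
    Negative branch-length estimates are clamped to zero.
    """
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 units")
    active = list(range(n))
    dist = d.astype(float).copy()
    next_id = n
    merges: list[tuple[int, int, float, float]] = []

    while len(active) > 3:
        m = len(active)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically-first argmin among exact ties
        flat = np.argmin(q, axis=None)
        i, j = np.unravel_index(flat, q.shape)
        if i > j:
            i, j = j, i
        li = dist[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        merges.append((active[i], active[j], li, lj))

        new_row = (dist[i, :] + dist[j, :] - dist[i, j]) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        new_dist = np.empty((m - 1, m - 1))
        new_dist[:-1, :-1] = dist[np.ix_(keep, keep)]
        new_dist[-1, :-1] = new_row[keep]
        new_dist[:-1, -1] = new_row[keep]
        new_dist[-1, -1] = 0.0
        active = [active[k] for k in keep] + [next_id]
        dist = new_dist
        next_id += 1

    # final three-way join: closed-form lengths to the central node
    a, b, c = active
    va = max((dist[0, 1] + dist[0, 2] - dist[1, 2]) / 2, 0.0)
    vb = max((dist[0, 1] + dist[1, 2] - dist[0, 2]) / 2, 0.0)
    vc = max((dist[0, 2] + dist[1, 2] - dist[0, 1]) / 2, 0.0)
    merges.append((a, b, va, vb))
    merges.append((next_id, c, 0.0, vc))
    return merges


def _merges_to_tree(merges, labels: list[str]) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace(labels)
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(labels):
        nodes[i] = dendropy.Node(taxon=ns.get_taxon(lab))
    next_id = len(labels)
    *body, last = merges
    for i, j, li, lj in body:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes[next_id] = parent
        next_id += 1
    # ``last`` attaches the final unit to the node created by the previous
    # merge, producing the unrooted trifurcation at the root
    root_id, c, _, vc = last
    root = nodes[root_id]
    root.add_child(nodes[c])
    nodes[c].edge.length = vc
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _nj_split_masks(d: np.ndarray, n_leaves: int) -> set[int]:
    """Internal-edge bipartitions of the NJ tree as canonical leaf bitmasks
    (side not containing leaf 0)."""
    full = (1 << n_leaves) - 1
    masks = {i: 1 << i for i in range(n_leaves)}
    splits: set[int] = set()
    merges = _nj_merges(d)
    next_id = n_leaves
    *body, last = merges
    for i, j, _, _ in body:
        m = masks[i] | masks[j]
        masks[next_id] = m
        next_id += 1
    for m in list(masks.values()):
        pc = bin(m).count("1")
        if 2 <= pc <= n_leaves - 2:
            splits.add(m if not (m & 1) else full ^ m)
    return splits


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Build the unrooted NJ tree for a distance matrix (>= 3 labels)."""
    merges = _nj_merges(dm.d)
    tree = _merges_to_tree(merges, dm.labels)
    return PhyloTree(tree=tree, labels=list(dm.labels))


def bootstrap_tree(dataset: GenotypeDataset, unit: str = "individual",
                   config: BootstrapConfig | None = None,
                   cap: float | None = None) -> PhyloTree:
    """Full-data NJ tree with locus-bootstrap supports on internal edges.

    Loci are resampled with replacement (same count) per replicate and the
    distance matrix and NJ tree recomputed; the support of each internal
    edge of the original tree is the percentage of replicates whose tree
    contains the same bipartition.  Replicates with undefined distances are
    redrawn (aborting after 10x the replicate count).
    """
    if dataset.n_loci < 1:
        raise ValueError("bootstrap needs >= 1 locus")
    config = config or BootstrapConfig()
    parts = _frequency_parts(dataset, unit)
    labels = parts.labels
    n = len(labels)
    d0 = parts.distances(cap=cap)
    tree = neighbor_joining(DistanceMatrix(labels=labels, d=d0))

    target_masks = _nj_split_masks(d0, n)
    hits = {m: 0 for m in target_masks}

    rng = np.random.default_rng(config.seed)
    done = attempts = 0
    redraws = 0
    L = dataset.n_loci
    while done < config.replicates:
        if attempts >= 10 * config.replicates:
            raise RuntimeError(
                f"too many bootstrap redraws ({redraws}); distances "
                "undefined in most resamples"
            )
        attempts += 1
        idx = rng.integers(0, L, size=L)
        try:
            d = parts.distances(locus_idx=idx, cap=cap)
        except ValueError:
            redraws += 1
            continue
        rep_masks = _nj_split_masks(d, n)
        for m in target_masks & rep_masks:
            hits[m] += 1
        done += 1

    all_labels = frozenset(labels)
    ref = min(labels)
    supports: dict[frozenset, float] = {}
    for m, h in hits.items():
        side = frozenset(labels[i] for i in range(n) if m >> i & 1)
        if ref in side:
            side = all_labels - side
        supports[side] = 100.0 * h / config.replicates

    # annotate internal nodes of the full-data tree
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = below if ref not in below else all_labels - below
        if key in supports:
            node.label = str(int(round(supports[key])))
    tree.supports = supports
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def write_newick(tree: PhyloTree, path, support_threshold: float | None = None) -> None:
    """Write Newick with 6-decimal branch lengths and integer supports as
    internal node labels; ``support_threshold`` suppresses weaker labels at
    rendering time only (the data model keeps them all)."""
    t = tree.tree.clone(depth=1)
    if support_threshold is not None:
        for node in t.preorder_node_iter():
            if node.is_leaf() or node.label is None:
                continue
            try:
                if float(node.label) < support_threshold:
                    node.label = None
            except ValueError:
                pass
    text = t.as_string(
        schema="newick",
        real_value_format_specifier=".6f",
        suppress_rooting=True,
        preserve_spaces=True,  # quote, rather than mangle, spaced labels
    )
    with open(path, "w") as fh:
        fh.write(text)


def read_newick(path) -> PhyloTree:
    """Read a Newick tree; numeric internal labels are parsed as supports."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    tree.is_rooted = False
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    out = PhyloTree(tree=tree, labels=labels)
    supports: dict[frozenset, float] = {}
    all_labels = frozenset(labels)
    ref = min(labels)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf() or node.label is None:
            continue
        try:
            val = float(node.label)
        except ValueError:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = below if ref not in below else all_labels - below
        supports[key] = val
    out.supports = supports or None
    return out
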