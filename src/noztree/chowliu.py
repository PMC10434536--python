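"""Chow-Liu tree learning over binned marker distributions.

The joint distribution of J binned markers is approximated by a tree-structured
Bayesian network: a root marginal times a product of first-order conditionals
Q(x_child | x_parent), one per tree edge. The tree is the spanning tree that
maximizes the total pairwise mutual information — the classical Chow-Liu
construction, which is the best tree-shaped approximation in KL divergence.

All count tables are stored as exact integers. Zero counts are meaningful:
the downstream NoZ statistic counts cells whose probability is *exactly* zero,
so no smoothing or pseudocounts are applied anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_preprocess import (
    OUT_OF_RANGE,
    BinnedTable,
    BinningSpec,
    CellTable,
    Normalizer,
    normalize_and_bin,
)


@dataclass(frozen=True)
class PairHistogram:
    """Joint bin counts for one marker pair.

    ``counts[a, b]`` is the number of cells with bin a in marker_j and bin b
    in marker_k. Cells carrying an OUT_OF_RANGE sentinel in either marker are
    excluded and tallied in ``n_excluded``.
    """

    marker_j: int
    marker_k: int
    counts: np.ndarray  # (n_bins, n_bins) int64
    total: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.sum() != self.total:
            raise ValueError("pair histogram counts do not sum to total")

    def transpose(self) -> "PairHistogram":
        return PairHistogram(
            self.marker_k, self.marker_j, self.counts.T, self.total, self.n_excluded
        )


@dataclass(frozen=True)
class MarginalHistogram:
    """Bin counts of a single marker."""

    marker_j: int
    counts: np.ndarray  # (n_bins,) int64
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.sum() != self.total:
            raise ValueError("marginal histogram counts do not sum to total")


@dataclass(frozen=True)
class DependencyTree:
    """Undirected spanning tree over marker indices with MI edge weights (bits)."""

    n_nodes: int
    edges: tuple[tuple[int, int, float], ...]  # (j, k, mi) with j < k
    root: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError("a spanning tree over J nodes has exactly J-1 edges")
        if any(w < -1e-12 for _, _, w in self.edges):
            raise ValueError("negative mutual-information edge weight")
        if not (0 <= self.root < self.n_nodes):
            raise ValueError("root outside node range")
        # connectivity + acyclicity follow from J-1 edges and one component
        parent = self.parent_map()
        if len(parent) != self.n_nodes - 1:
            raise ValueError("edges do not form a connected tree")

    @property
    def total_mi(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def parent_map(self, root: Optional[int] = None) -> dict[int, int]:
        """Orient the tree away from ``root``: child -> parent for every non-root."""
        if root is None:
            root = self.root
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for j, k, _ in self.edges:
            adj[j].append(k)
            adj[k].append(j)
        parent: dict[int, int] = {}
        stack, seen = [root], {root}
        while stack:
            node = stack.pop()
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    parent[nxt] = node
                    stack.append(nxt)
        return parent


def pair_histogram(binned: BinnedTable, j: int, k: int) -> PairHistogram:
    """Tally the joint bin histogram of markers ``j`` and ``k``.

    Cells with an OUT_OF_RANGE sentinel in either marker are excluded; an
    empty intersection (every cell excluded) is an error because a zero-total
    histogram has no defined distribution.
    """
    if j == k:
        raise ValueError("pair histogram requires two distinct markers")
    nb = binned.binning_spec.n_bins
    bj = binned.bin_indices[:, j]
    bk = binned.bin_indices[:, k]
    keep = (bj != OUT_OF_RANGE) & (bk != OUT_OF_RANGE)
    n_excluded = int((~keep).sum())
    bj, bk = bj[keep], bk[keep]
    if bj.size == 0:
        raise ValueError(
            f"no cells left for marker pair ({j}, {k}) after sentinel exclusion"
        )
    counts = np.bincount(bj * nb + bk, minlength=nb * nb).reshape(nb, nb)
    return PairHistogram(j, k, counts, int(bj.size), n_excluded)


def marginal_histogram(binned: BinnedTable, j: int) -> MarginalHistogram:
    """Bin histogram of a single marker (sentinels excluded)."""
    nb = binned.binning_spec.n_bins
    bj = binned.bin_indices[:, j]
    bj = bj[bj != OUT_OF_RANGE]
    if bj.size == 0:
        raise ValueError(f"no in-range cells for marker {j}")
    counts = np.bincount(bj, minlength=nb)
    return MarginalHistogram(j, counts, int(bj.size))


def mutual_information(ph: PairHistogram) -> float:
    """Plug-in mutual information of a pair histogram, in bits.

    MI = sum_ab p(a,b) log2[ p(a,b) / (p(a) p(b)) ] with the convention
    0 * log(.) = 0. Non-negative up to floating-point round-off and symmetric
    under transposition.
    """
    if ph.total <= 0:
        raise ValueError("mutual information of a zero-total histogram is undefined")
    p = ph.counts / ph.total
    pj = p.sum(axis=1, keepdims=True)
    pk = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = np.where(mask, p, 1.0) / np.where(mask, pj * pk, 1.0)
    mi = float(np.sum(np.where(mask, p * np.log2(ratio), 0.0)))
    return max(mi, 0.0)  # clamp tiny negative round-off


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def all_pairwise_mi(binned: BinnedTable) -> dict[tuple[int, int], float]:
    """Mutual information of every marker pair (J(J-1)/2 values), in bits."""
    J = binned.n_markers
    return {
        (j, k): mutual_information(pair_histogram(binned, j, k))
        for j in range(J)
        for k in range(j + 1, J)
    }


def build_dependency_tree(binned: BinnedTable) -> DependencyTree:
    """Chow-Liu tree: maximum-MI spanning tree via Kruskal's algorithm.

    Edge candidates are sorted by (-MI, j, k) so ties are broken
    lexicographically, making the tree deterministic. The root is the lowest
    marker index; the tree-factorized probability does not depend on the
    rooting, so any deterministic convention works.
    """
    J = binned.n_markers
    if J < 2:
        raise ValueError("need at least two markers to build a tree")
    mi = all_pairwise_mi(binned)
    candidates = sorted(mi.items(), key=lambda item: (-item[1], item[0]))
    uf = _UnionFind(J)
    edges: list[tuple[int, int, float]] = []
    for (j, k), w in candidates:
        if uf.union(j, k):
            edges.append((j, k, w))
            if len(edges) == J - 1:
                break
    return DependencyTree(J, tuple(edges), root=0)


@dataclass(frozen=True)
class TreeModel:
    """A fitted tree Bayesian network over binned marker space.

    Stores the dependency tree, the integer joint-count grid of every tree
    edge, the root marginal counts, the binning spec and normalization policy,
    and training provenance. Edge grids are keyed by the sorted marker pair
    (a, b), a < b, with ``grid[bin_a, bin_b]``; the orientation needed for a
    conditional Q(child | parent) is derived from the rooting at evaluation
    time, which makes re-rooting a metadata change only.
    """

    marker_names: tuple[str, ...]
    binning_spec: BinningSpec
    normalization: str  # {per_file, from_training}
    tree: DependencyTree
    edge_counts: dict[tuple[int, int], np.ndarray]
    root_marginal: np.ndarray  # (n_bins,) int64
    n_training_cells: int
    normalizer: Optional[Normalizer] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        object.__setattr__(
            self,
            "edge_counts",
            {
                (min(a, b), max(a, b)): np.asarray(
                    g if a < b else g.T, dtype=np.int64
                )
                for (a, b), g in self.edge_counts.items()
            },
        )
        object.__setattr__(
            self, "root_marginal", np.asarray(self.root_marginal, dtype=np.int64)
        )
        if self.normalization == "from_training" and self.normalizer is None:
            raise ValueError("from_training normalization requires a stored normalizer")
        for (a, b), g in self.edge_counts.items():
            if g.sum() != self.n_training_cells:
                raise ValueError(f"edge ({a},{b}) grid total != training cell count")
        if self.root_marginal.sum() != self.n_training_cells:
            raise ValueError("root marginal total != training cell count")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def n_bins(self) -> int:
        return self.binning_spec.n_bins

    def edge_grid(self, child: int, parent: int) -> np.ndarray:
        """Joint count grid oriented ``grid[bin_child, bin_parent]``."""
        a, b = (child, parent) if child < parent else (parent, child)
        g = self.edge_counts[(a, b)]
        return g if child < parent else g.T

    def marginal(self, j: int) -> np.ndarray:
        """Training bin counts of marker ``j``, recovered from the stored grids."""
        if j == self.tree.root:
            # the root marginal is stored directly; consistent with the grids
            return self.root_marginal
        a, b = next(
            (a, b) for (a, b) in self.edge_counts if j in (a, b)
        )
        g = self.edge_counts[(a, b)]
        return g.sum(axis=1) if j == a else g.sum(axis=0)

    def reroot(self, new_root: int) -> "TreeModel":
        """Same model rooted at a different marker; per-cell probabilities are
        unchanged, only the factorization order differs."""
        tree = DependencyTree(self.tree.n_nodes, self.tree.edges, new_root)
        rm = marginal_from_grids(self.edge_counts, new_root)
        return TreeModel(
            self.marker_names,
            self.binning_spec,
            self.normalization,
            tree,
            self.edge_counts,
            rm,
            self.n_training_cells,
            self.normalizer,
            dict(self.provenance),
        )

    def merge_bins(self, factor: int = 2) -> "TreeModel":
        """Coarsen the binning by summing ``factor`` adjacent bins, keeping the tree.

        Because bin indices nest exactly (bin at Nx/f equals bin at Nx floored
        by f), any cell with zero probability under the merged model also has
        zero probability under the fine model.
        """
        nb = self.n_bins
        if nb % factor != 0:
            raise ValueError(f"n_bins={nb} not divisible by merge factor {factor}")
        m = nb // factor
        merged = {
            e: g.reshape(m, factor, m, factor).sum(axis=(1, 3))
            for e, g in self.edge_counts.items()
        }
        spec = BinningSpec(m, self.binning_spec.oob_policy)
        tree = self.tree
        rm = self.root_marginal.reshape(m, factor).sum(axis=1)
        return TreeModel(
            self.marker_names,
            spec,
            self.normalization,
            tree,
            merged,
            rm,
            self.n_training_cells,
            self.normalizer,
            {**self.provenance, "merged_from_n_bins": nb},
        )

    # ---------------------------------------------------------------- io ----
    def to_dict(self) -> dict:
        d = {
            "marker_names": list(self.marker_names),
            "n_bins": self.binning_spec.n_bins,
            "oob_policy": self.binning_spec.oob_policy,
            "normalization": self.normalization,
            "tree": {
                "n_nodes": self.tree.n_nodes,
                "root": self.tree.root,
                "edges": [[j, k, w] for j, k, w in self.tree.edges],
            },
            "edge_counts": {
                f"{a},{b}": g.tolist() for (a, b), g in sorted(self.edge_counts.items())
            },
            "root_marginal": self.root_marginal.tolist(),
            "n_training_cells": self.n_training_cells,
            "provenance": self.provenance,
        }
        if self.normalizer is not None:
            d["normalizer"] = {
                "minima": self.normalizer.minima.tolist(),
                "maxima": self.normalizer.maxima.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        spec = BinningSpec(int(d["n_bins"]), d.get("oob_policy", "clip"))
        tree = DependencyTree(
            int(d["tree"]["n_nodes"]),
            tuple((int(j), int(k), float(w)) for j, k, w in d["tree"]["edges"]),
            int(d["tree"]["root"]),
        )
        edge_counts = {}
        for key, grid in d["edge_counts"].items():
            a, b = (int(x) for x in key.split(","))
            edge_counts[(a, b)] = np.asarray(grid, dtype=np.int64)
        normalizer = None
        if "normalizer" in d:
            normalizer = Normalizer(
                tuple(d["marker_names"]),
                np.asarray(d["normalizer"]["minima"]),
                np.asarray(d["normalizer"]["maxima"]),
                policy="from_training",
            )
        return cls(
            tuple(d["marker_names"]),
            spec,
            d["normalization"],
            tree,
            edge_counts,
            np.asarray(d["root_marginal"], dtype=np.int64),
            int(d["n_training_cells"]),
            normalizer,
            dict(d.get("provenance", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TreeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def marginal_from_grids(
    edge_counts: dict[tuple[int, int], np.ndarray], j: int
) -> np.ndarray:
    """Marginal counts of marker ``j`` from any edge grid that touches it."""
    for (a, b), g in edge_counts.items():
        if j == a:
            return np.asarray(g, dtype=np.int64).sum(axis=1)
        if j == b:
            return np.asarray(g, dtype=np.int64).sum(axis=0)
    raise KeyError(f"marker {j} touches no stored edge")


def fit_tree_model(
    pool: CellTable,
    spec: BinningSpec,
    marker_subset: Optional[Sequence[str]] = None,
    normalization: str = "per_file",
    provenance: Optional[dict] = None,
) -> TreeModel:
    """Fit the control-tree model on a pooled cohort.

    Normalizes and bins the pool, learns the Chow-Liu dependency tree, and
    stores exact integer count tables: one joint grid per tree edge plus the
    root marginal. With ``normalization="from_training"`` the pool's
    column-wise min/max are kept in the model and applied to test samples;
    with ``"per_file"`` (default) every scored sample is normalized by its own
    column range.
    """
    if normalization not in ("per_file", "from_training"):
        raise ValueError(f"unknown normalization policy {normalization!r}")
    if marker_subset is not None:
        pool = pool.select_markers(list(marker_subset))
    binned, used_norm = normalize_and_bin(pool, spec)
    tree = build_dependency_tree(binned)
    edge_counts = {
        (j, k): pair_histogram(binned, j, k).counts for j, k, _ in tree.edges
    }
    root_marginal = marginal_histogram(binned, tree.root).counts
    stored_norm = None
    if normalization == "from_training":
        stored_norm = Normalizer(
            used_norm.marker_names,
            used_norm.minima,
            used_norm.maxima,
            policy="from_training",
        )
    prov = dict(provenance or {})
    prov.setdefault("pooled_sample_id", pool.sample_id)
    prov.setdefault("n_training_cells", pool.n_cells)
    return TreeModel(
        pool.marker_names,
        spec,
        normalization,
        tree,
        edge_counts,
        root_marginal,
        pool.n_cells,
        stored_norm,
        prov,
    )
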