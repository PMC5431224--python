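"""Agglomerative hierarchical clustering with dendrogram-cutoff partitions.

The agglomeration is implemented directly via the Lance-Williams updates so
that tie-breaking is fully deterministic: when several pairs attain the
minimal distance, the pair with the lexicographically smallest
(lower slot index, higher slot index) is merged. ward_d2 follows the
Murtagh-Legendre definition (update on squared distances, heights reported
on the original distance scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import SizeLimitError, ValidationError
from .genesets import GeneSet

LINKAGE_METHODS = ("ward_d2", "average", "complete", "single")
DISTANCES = ("pearson", "euclidean")

#: hard cap on the number of gene rows a single clustering accepts
MAX_CLUSTER_GENES = 1000


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree over ``n_leaves`` labelled leaves.

    Node ids follow the usual convention: leaves are 0..n-1 and the i-th
    merge creates node n+i.
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float], ...]
    leaf_labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValidationError(
                f"expected {self.n_leaves - 1} merges, got {len(self.merges)}"
            )
        if len(self.leaf_labels) != self.n_leaves:
            raise ValidationError("leaf_labels length must equal n_leaves")
        seen = set()
        for left, right, _ in self.merges:
            for node in (left, right):
                if node in seen:
                    raise ValidationError(f"node {node} merged twice")
                seen.add(node)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    @property
    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf ordering implied by the merge tree."""
        if self.n_leaves == 1:
            return [0]
        children = {
            self.n_leaves + i: (l, r) for i, (l, r, _) in enumerate(self.merges)
        }
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right = children[node]
                stack.append(right)
                stack.append(left)
        return order


@dataclass(frozen=True)
class ClusterPartition:
    """Cutoff-derived partition; clusters indexed cluster1..K in
    dendrogram (left-to-right) order."""

    cutoff: float
    clusters: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        all_members = [m for c in self.clusters for m in c]
        if len(set(all_members)) != len(all_members):
            raise ValidationError("partition clusters must be disjoint")
        if not self.clusters:
            raise ValidationError("partition must have at least one cluster")

    @property
    def names(self) -> list[str]:
        return [f"cluster{i + 1}" for i in range(len(self.clusters))]

    def labels(self) -> dict[str, str]:
        return {m: name for name, c in zip(self.names, self.clusters) for m in c}

    def to_gene_sets(self, provenance: str = "") -> list[GeneSet]:
        return [
            GeneSet(name=name, members=members, provenance=provenance)
            for name, members in zip(self.names, self.clusters)
        ]


@dataclass(frozen=True)
class ClusteringConfig:
    method: str = "ward_d2"
    distance: str = "pearson"
    axis: str = "rows"
    max_genes: int = MAX_CLUSTER_GENES

    def __post_init__(self):
        if self.method not in LINKAGE_METHODS:
            raise ValidationError(f"unknown linkage method {self.method!r}")
        if self.distance not in DISTANCES:
            raise ValidationError(f"unknown distance {self.distance!r}")
        if self.axis not in ("rows", "columns", "both"):
            raise ValidationError(f"unknown axis {self.axis!r}")
        if self.max_genes <= 0:
            raise ValidationError("max_genes must be positive")


@dataclass(frozen=True)
class ClusteringResult:
    row_dendrogram: Dendrogram
    column_dendrogram: Dendrogram | None = None
    partition: ClusterPartition | None = None
    gene_sets: tuple[GeneSet, ...] = field(default_factory=tuple)


def pearson_distance_matrix(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation over rows; range [0, 2]."""
    if isinstance(table, pd.DataFrame):
        labels = list(table.index)
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        labels = [str(i) for i in range(x.shape[0])]
    if x.shape[1] < 2:
        raise ValidationError("need >= 2 columns for a correlation distance")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = labels[int(np.argmax(sd == 0))]
        raise ValidationError(
            f"constant row {bad!r}: Pearson correlation is undefined"
        )
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def euclidean_distance_matrix(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    x = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    return squareform(pdist(x, metric="euclidean"))


def hierarchical_cluster(
    dist: np.ndarray,
    method: str = "ward_d2",
    leaf_labels: list[str] | None = None,
    max_leaves: int | None = None,
) -> Dendrogram:
    """Agglomerate a symmetric distance matrix into a Dendrogram."""
    if method not in LINKAGE_METHODS:
        raise ValidationError(f"unknown linkage method {method!r}")
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValidationError("distance matrix must be square")
    n = dist.shape[0]
    if max_leaves is not None and n > max_leaves:
        raise SizeLimitError(
            f"clustering is limited to sets of {max_leaves} genes or less "
            f"(got {n} rows)"
        )
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValidationError("distance matrix must have a zero diagonal")
    if leaf_labels is None:
        leaf_labels = [str(i) for i in range(n)]
    if len(leaf_labels) != n:
        raise ValidationError("leaf_labels length must match matrix size")
    if n == 1:
        return Dendrogram(1, (), tuple(leaf_labels))

    work = dist.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    node_id = np.arange(n)
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        # row-major argmin over the full symmetric matrix picks the
        # lexicographically smallest (i, j) pair among ties
        flat = int(np.argmin(work))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = float(work[i, j])
        merges.append((int(node_id[i]), int(node_id[j]), h))

        si, sj = sizes[i], sizes[j]
        others = active.copy()
        others[i] = others[j] = False
        if others.any():
            di = work[i, others]
            dj = work[j, others]
            if method == "single":
                new = np.minimum(di, dj)
            elif method == "complete":
                new = np.maximum(di, dj)
            elif method == "average":
                new = (si * di + sj * dj) / (si + sj)
            else:  # ward_d2 (Lance-Williams on squared distances)
                sk = sizes[others]
                new = np.sqrt(
                    ((si + sk) * di**2 + (sj + sk) * dj**2 - sk * h**2)
                    / (si + sj + sk)
                )
            work[i, others] = new
            work[others, i] = new
        sizes[i] = si + sj
        node_id[i] = n + step
        active[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf
        work[i, i] = np.inf

    return Dendrogram(n, tuple(merges), tuple(leaf_labels))


def cut_dendrogram(dend: Dendrogram, cutoff: float) -> ClusterPartition:
    """Partition leaves: two leaves share a cluster iff their lowest common
    merge has height <= cutoff."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    n = dend.n_leaves
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (left, right, h) in enumerate(dend.merges):
        node = n + i
        if h <= cutoff:
            parent[find(left)] = node
            parent[find(right)] = node
        else:
            # still record the tree node so later merges can reference it,
            # but do not join the children's components
            parent[node] = node

    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    # order clusters by first appearance in the dendrogram's leaf order
    order = dend.leaf_order()
    rank = {leaf: pos for pos, leaf in enumerate(order)}
    sorted_groups = sorted(groups.values(), key=lambda g: min(rank[x] for x in g))
    clusters = tuple(
        tuple(dend.leaf_labels[leaf] for leaf in sorted(g, key=lambda x: rank[x]))
        for g in sorted_groups
    )
    return ClusterPartition(cutoff=float(cutoff), clusters=clusters)


def _distance_matrix(table: pd.DataFrame, distance: str, axis: str) -> np.ndarray:
    data = table if axis == "rows" else table.T
    if distance == "pearson":
        return pearson_distance_matrix(data)
    return euclidean_distance_matrix(data)


def cluster_table(
    table: pd.DataFrame,
    config: ClusteringConfig = ClusteringConfig(),
    cutoff: float | None = None,
) -> ClusteringResult:
    """Distance -> linkage -> optional cut, per configured axis.

    Row clusters (when a cutoff is given) are emitted as GeneSets named
    cluster1..K in dendrogram order.
    """
    if len(table) > config.max_genes:
        raise SizeLimitError(
            f"clustering is limited to sets of {config.max_genes} genes or "
            f"less (got {len(table)} rows)"
        )
    row_dend = None
    col_dend = None
    if config.axis in ("rows", "both"):
        d = _distance_matrix(table, config.distance, "rows")
        row_dend = hierarchical_cluster(
            d, config.method, leaf_labels=[str(i) for i in table.index],
            max_leaves=config.max_genes,
        )
    if config.axis in ("columns", "both"):
        d = _distance_matrix(table, config.distance, "columns")
        col_dend = hierarchical_cluster(
            d, config.method, leaf_labels=[str(c) for c in table.columns]
        )
    if row_dend is None:
        raise ValidationError("row clustering is required for partitioning")
    partition = None
    gene_sets: tuple[GeneSet, ...] = ()
    if cutoff is not None:
        partition = cut_dendrogram(row_dend, cutoff)
        prov = (
            f"cluster method={config.method} distance={config.distance} "
            f"cutoff={cutoff:g}"
        )
        gene_sets = tuple(partition.to_gene_sets(provenance=prov))
    return ClusteringResult(
        row_dendrogram=row_dend,
        column_dendrogram=col_dend,
        partition=partition,
        gene_sets=gene_sets,
    )
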