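"""Gene-set over-representation against GMT annotation collections.

The statistic is the one-sided hypergeometric upper tail P[X >= k]
(over-representation). Adjustment across the tested categories is
Benjamini-Hochberg by default; Holm and no adjustment are also available.
The per-cluster quick summary reports RAW p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .clustering import ClusterPartition
from .errors import ValidationError
from .genesets import GeneSet

FEATURE_TYPES = ("pathway", "go_term", "goslim", "ipc", "other")
ADJUSTMENTS = ("bh", "holm", "none")

#: EnrichmentResult column layout
RESULT_COLUMNS = [
    "category",
    "description",
    "universe_size",
    "category_size",
    "query_size",
    "overlap",
    "p_raw",
    "p_adj",
]


@dataclass(frozen=True)
class AnnotationCollection:
    """Named categories (e.g. pathways or GO terms) over gene IDs."""

    name: str
    feature_type: str
    categories: Mapping[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.feature_type not in FEATURE_TYPES:
            raise ValidationError(f"unknown feature type {self.feature_type!r}")
        if not self.categories:
            raise ValidationError(f"collection {self.name!r} has no categories")
        for cid, (_, members) in self.categories.items():
            if len(set(members)) != len(members):
                raise ValidationError(f"category {cid!r} has duplicate members")

    def members(self, category_id: str) -> set[str]:
        return set(self.categories[category_id][1])


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact hypergeometric upper-tail probability P[X >= k].

    ``N`` universe size, ``K`` category size, ``n`` query size, ``k``
    observed overlap.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValidationError(
            f"inconsistent counts: N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * (m - np.arange(m))
    adj = np.maximum.accumulate(ranked)
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def enrich(
    query: GeneSet,
    universe: GeneSet,
    collection: AnnotationCollection,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Over-representation of ``query`` in each category, vs ``universe``.

    Genes absent from the universe are dropped from the query with a
    warning. One row per category with at least one universe member; rows
    sorted by raw p ascending. Columns follow ``RESULT_COLUMNS``.
    """
    if adjust not in ADJUSTMENTS:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    uni = set(universe.members)
    q = [g for g in query.members if g in uni]
    dropped = len(query.members) - len(q)
    if dropped:
        warnings.warn(f"{dropped} query genes absent from the universe were dropped")
    if not q:
        raise ValidationError("effective query is empty after universe intersection")
    qset = set(q)
    N, n = len(uni), len(qset)
    rows = []
    for cid in sorted(collection.categories):
        desc, members = collection.categories[cid]
        cat = set(members) & uni
        if not cat:
            continue
        K = len(cat)
        k = len(cat & qset)
        rows.append((cid, desc, N, K, n, k, hypergeom_tail(N, K, n, k)))
    if not rows:
        raise ValidationError("no collection category overlaps the universe")
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    p = df["p_raw"].to_numpy()
    if adjust == "bh":
        df["p_adj"] = bh_adjust(p)
    elif adjust == "holm":
        df["p_adj"] = holm_adjust(p)
    else:
        df["p_adj"] = p
    df = df.sort_values("p_raw", kind="stable", ignore_index=True)
    return df


def top_feature_per_cluster(
    partition: ClusterPartition,
    universe: GeneSet,
    collection: AnnotationCollection,
) -> dict[str, tuple[str, float] | None]:
    """For each cluster, the single most enriched category and its RAW p.

    Tie-break: smaller raw p, then larger overlap k, then lexicographically
    smaller category ID. Clusters with no testable category map to None.
    """
    out: dict[str, tuple[str, float] | None] = {}
    for name, members in zip(partition.names, partition.clusters):
        cluster_set = GeneSet(name=name, members=members)
        try:
            table = enrich(cluster_set, universe, collection, adjust="none")
        except ValidationError:
            out[name] = None
            continue
        best = table.sort_values(
            ["p_raw", "overlap", "category"],
            ascending=[True, False, True],
            kind="stable",
        ).iloc[0]
        out[name] = (str(best["category"]), float(best["p_raw"]))
    return out
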