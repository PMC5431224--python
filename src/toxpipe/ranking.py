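"""Compound ranking: order compounds by how consistently they up- or
downregulate a query gene set.

The default score for ``total_downregulation`` is the mean over query genes
and scoped conditions of -log2(fold); ``total_upregulation`` is the mean of
+log2(fold). Higher score = stronger match. The scorer is pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .core import ExpressionDataset, group_fold_columns, group_from_factors
from .errors import ValidationError
from .genesets import GeneSet

MODES = ("total_upregulation", "total_downregulation")

#: (fold table restricted to query genes, sign) -> score
Scorer = Callable[[pd.DataFrame, int], float]


@dataclass(frozen=True)
class RankingQuery:
    gene_set: GeneSet
    mode: str = "total_downregulation"
    scope: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"unknown ranking mode {self.mode!r}")
        if not self.gene_set.members:
            raise ValidationError("ranking query gene set must be non-empty")

    @property
    def sign(self) -> int:
        return -1 if self.mode == "total_downregulation" else 1


def mean_log2_scorer(folds: pd.DataFrame, sign: int) -> float:
    """Mean of sign * log2(fold) over all genes and conditions."""
    values = np.log2(folds.to_numpy(dtype=float))
    return float(sign * np.nanmean(values))


def compound_score(
    folds: pd.DataFrame,
    query: RankingQuery,
    scorer: Scorer = mean_log2_scorer,
) -> tuple[float, int, int]:
    """Score one compound's probes x conditions fold table against the query.

    Query genes absent from the table are dropped with a warning. Returns
    (score, genes_used, conditions_used).
    """
    present = [g for g in query.gene_set.members if g in folds.index]
    dropped = len(query.gene_set.members) - len(present)
    if dropped:
        warnings.warn(f"{dropped} query genes missing from the compound's data")
    if not present:
        raise ValidationError("no overlap between query genes and compound data")
    sub = folds.loc[present]
    return scorer(sub, query.sign), len(present), sub.shape[1]


def compound_fold_tables(
    dataset: ExpressionDataset,
    dose_level: str = "Middle",
    scope: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-compound probes x time-point tables of group-mean fold values.

    Each cell is the arithmetic mean over the group's per-sample folds
    (pre-log), computed against the matched control group. ``scope``
    filters on metadata fields (organ, test_type, species, ...).
    """
    scope = dict(scope or {})
    samples = [
        s
        for s in dataset.samples
        if s.dose_level == dose_level
        and all(getattr(s, k) == v for k, v in scope.items())
    ]
    by_compound: dict[str, dict[str, list]] = {}
    for s in samples:
        by_compound.setdefault(s.compound, {}).setdefault(s.exposure_time, []).append(s)
    tables = {}
    for compound, times in sorted(by_compound.items()):
        cols = {}
        for time in sorted(times):
            group = group_from_factors(
                dataset,
                name=f"{compound}/{dose_level}/{time}",
                compound=compound,
                dose_level=dose_level,
                exposure_time=time,
                **scope,
            )
            cols[time] = group_fold_columns(dataset, group).mean(axis=1)
        tables[compound] = pd.DataFrame(cols, index=dataset.probes)
    return tables


def rank_compounds(
    fold_tables: Mapping[str, pd.DataFrame],
    query: RankingQuery,
    scorer: Scorer = mean_log2_scorer,
) -> pd.DataFrame:
    """Rank compounds by descending score; ties broken by compound name.

    Compounds with no query-gene overlap are excluded and reported.
    Columns: rank, compound, score, genes_used, conditions_used.
    """
    if len(fold_tables) < 2:
        raise ValidationError("compound ranking needs at least 2 compounds in scope")
    rows = []
    excluded = []
    for compound in sorted(fold_tables):
        try:
            score, genes, conds = compound_score(fold_tables[compound], query, scorer)
        except ValidationError:
            excluded.append(compound)
            continue
        rows.append((compound, score, genes, conds))
    if excluded:
        warnings.warn(f"compounds excluded (no query overlap): {excluded}")
    if not rows:
        raise ValidationError("no compound overlaps the query gene set")
    df = pd.DataFrame(rows, columns=["compound", "score", "genes_used", "conditions_used"])
    df = df.sort_values(
        ["score", "compound"], ascending=[False, True], kind="stable", ignore_index=True
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
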