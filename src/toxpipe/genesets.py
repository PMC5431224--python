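"""Gene-set discovery: column filters, statistical test columns, the
consistent up/down-regulation extraction rule, and set algebra.

Filter bounds are inclusive on both sides. Multiple column filters combine
by conjunction. Test p-values are two-sided and are not multiplicity
adjusted here (adjustment lives in the enrichment module).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionDataset, SampleGroup
from .errors import UndefinedTestError, ValidationError

FILTER_KINDS = ("upper", "upper_abs", "lower", "lower_abs")
TESTS = ("welch_t", "mann_whitney_u")

#: pooled-size threshold below which the Mann-Whitney p is computed by
#: exhaustive enumeration of group labelings
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class ColumnFilter:
    """One bound on one table column; inactive filters pass everything."""

    kind: str
    threshold: float
    active: bool = True

    def __post_init__(self):
        if self.kind not in FILTER_KINDS:
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        if not math.isfinite(self.threshold):
            raise ValidationError("filter threshold must be finite")


@dataclass(frozen=True)
class GeneSet:
    """An ordered, named collection of probe/gene IDs with provenance."""

    name: str
    members: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if len(set(self.members)) != len(self.members):
            dups = sorted({m for m in self.members if self.members.count(m) > 1})
            raise ValidationError(f"gene set {self.name!r}: duplicate members {dups}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in set(self.members)


@dataclass(frozen=True)
class StatColumn:
    """Probe-indexed p-values comparing two sample groups."""

    test: str
    group_a: str
    group_b: str
    values: pd.Series = field(compare=False)

    def __post_init__(self):
        if self.test not in TESTS:
            raise ValidationError(f"unknown test {self.test!r}")
        finite = self.values.dropna()
        if ((finite < 0) | (finite > 1)).any():
            raise ValidationError("p-values must lie in [0, 1]")


def apply_filter(values, flt: ColumnFilter) -> np.ndarray:
    """Boolean mask of entries passing the (inclusive) bound.

    Missing values fail any active filter.
    """
    v = np.asarray(values, dtype=float)
    if not flt.active:
        return np.ones(v.shape, dtype=bool)
    t = flt.threshold
    if flt.kind == "upper":
        mask = v <= t
    elif flt.kind == "upper_abs":
        mask = np.abs(v) <= t
    elif flt.kind == "lower":
        mask = v >= t
    else:  # lower_abs
        mask = np.abs(v) >= t
    return mask & ~np.isnan(v)


def filter_table(
    table: pd.DataFrame,
    filters: dict[str, ColumnFilter],
    name: str = "filtered",
) -> GeneSet:
    """AND the active column filters over a probes x columns table.

    Row order of the result follows the table's current order.
    """
    unknown = [c for c in filters if c not in table.columns]
    if unknown:
        raise ValidationError(f"unknown filter columns: {sorted(unknown)}")
    mask = np.ones(len(table), dtype=bool)
    steps = []
    for col, flt in filters.items():
        mask &= apply_filter(table[col].to_numpy(), flt)
        state = "active" if flt.active else "inactive"
        steps.append(f"{col}: {flt.kind} {flt.threshold:g} ({state})")
    members = tuple(table.index[mask])
    if not members:
        warnings.warn(f"filter produced an empty gene set ({'; '.join(steps)})")
    return GeneSet(name=name, members=members, provenance="filter " + "; ".join(steps))


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedTestError(
            f"Welch t-test needs >= 2 values per group (got {a.size} and {b.size})"
        )
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise UndefinedTestError("Welch t-test undefined: zero variance in both groups")
    sa, sb = va / a.size, vb / b.size
    se = math.sqrt(sa + sb)
    t = (a.mean() - b.mean()) / se
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a_i, b_j) pairs with a_i > b_j, ties 0.5."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U-test, two-sided.

    Exact p by enumerating all group labelings when the pooled size is at
    most ``EXACT_MW_LIMIT``; otherwise a normal approximation with tie and
    continuity corrections. Extremeness for the exact rule is the absolute
    deviation of U from its null mean n_a * n_b / 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise UndefinedTestError("Mann-Whitney needs >= 1 value per group")
    na, nb = a.size, b.size
    u = _u_statistic(a, b)
    mu = na * nb / 2.0
    if na + nb <= EXACT_MW_LIMIT:
        pooled = np.concatenate([a, b])
        n = na + nb
        observed = abs(u - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n), na):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            u_perm = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u_perm - mu) >= observed - 1e-12:
                hits += 1
        return u, hits / total
    # normal approximation with tie correction
    n = na + nb
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sd = math.sqrt(na * nb / 12.0 * ((n + 1) - tie_term))
    if sd == 0:
        return u, 1.0
    num = max(abs(u - mu) - 0.5, 0.0)  # continuity correction
    p = 2.0 * stats.norm.sf(num / sd)
    return u, float(min(p, 1.0))


def compute_stat_column(
    dataset: ExpressionDataset,
    group_a: SampleGroup,
    group_b: SampleGroup,
    test: str = "welch_t",
) -> StatColumn:
    """Per-probe p-values comparing two groups' sample intensities.

    Probes where the test is undefined get NaN and are reported in a
    warning rather than aborting the whole column.
    """
    if test not in TESTS:
        raise ValidationError(f"unknown test {test!r}")
    va = dataset.columns(group_a.sample_ids)
    vb = dataset.columns(group_b.sample_ids)
    p = np.full(dataset.n_probes, np.nan)
    undefined = []
    for i in range(dataset.n_probes):
        try:
            if test == "welch_t":
                _, _, p[i] = welch_t(va[i], vb[i])
            else:
                _, p[i] = mann_whitney(va[i], vb[i])
        except UndefinedTestError:
            undefined.append(dataset.probes[i])
    if undefined:
        warnings.warn(
            f"{test} undefined for {len(undefined)} probes "
            f"(first: {undefined[:5]}); reported as NaN"
        )
    values = pd.Series(p, index=dataset.probes, name=f"{test}({group_a.name},{group_b.name})")
    return StatColumn(test=test, group_a=group_a.name, group_b=group_b.name, values=values)


def extract_consistent(
    folds: pd.DataFrame,
    ratio: float,
    direction: str = "down",
    name: str | None = None,
) -> GeneSet:
    """Probes whose fold change passes the ratio at ALL time points.

    ``folds`` is a probes x time-points table of pre-log fold values.
    ``direction='down'`` keeps probes with fold <= ratio everywhere
    (boundary inclusive, so a fold of exactly ``ratio`` passes);
    ``direction='up'`` keeps probes with fold >= 1/ratio everywhere.
    Probes with a missing time point are excluded and reported.
    """
    if folds.shape[1] < 1:
        raise ValidationError("need at least one time point")
    if ratio <= 0:
        raise ValidationError("ratio must be positive")
    if direction not in ("down", "up"):
        raise ValidationError(f"direction must be 'down' or 'up', got {direction!r}")
    values = folds.to_numpy(dtype=float)
    missing = np.isnan(values).any(axis=1)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} probes excluded for missing time points "
            f"(first: {list(folds.index[missing][:5])})"
        )
    if direction == "down":
        keep = np.all(values <= ratio, axis=1)
    else:
        keep = np.all(values >= 1.0 / ratio, axis=1)
    keep &= ~missing
    if name is None:
        name = f"consistent_{direction}"
    prov = (
        f"extract_consistent direction={direction} ratio={ratio:g} "
        f"time_points={list(folds.columns)}"
    )
    return GeneSet(name=name, members=tuple(folds.index[keep]), provenance=prov)


def geneset_algebra(a: GeneSet, b: GeneSet, op: str) -> GeneSet:
    """union / intersect / difference with stable ordering: members of
    ``a`` first (in a's order), then new members of ``b`` in b's order."""
    sa, sb = set(a.members), set(b.members)
    if op == "union":
        members = a.members + tuple(m for m in b.members if m not in sa)
    elif op == "intersect":
        members = tuple(m for m in a.members if m in sb)
    elif op == "difference":
        members = tuple(m for m in a.members if m not in sb)
    else:
        raise ValidationError(f"unknown set operation {op!r}")
    return GeneSet(
        name=f"{a.name}_{op}_{b.name}",
        members=members,
        provenance=f"{op}({a.name}, {b.name})",
    )
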