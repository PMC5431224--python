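"""Cross-species display: collapse ortholog probe sets to single rows.

A row value is the median of the contributing probes' per-group averages
("median of averages"); an even count of contributors uses the mean of the
two middle values. Cells with no contributing probe are NA, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class OrthologMap:
    """Disjoint cross-platform probe sets: set_id -> [(platform, probe)]."""

    sets: tuple[tuple[str, tuple[tuple[str, str], ...]], ...]
    provenance: str = ""

    def __post_init__(self):
        seen: dict[tuple[str, str], str] = {}
        for set_id, members in self.sets:
            if not members:
                raise ValidationError(f"ortholog set {set_id!r} is empty")
            for platform, probe in members:
                key = (platform, probe)
                if key in seen:
                    raise ValidationError(
                        f"probe {probe!r} on platform {platform!r} appears in "
                        f"both {seen[key]!r} and {set_id!r}"
                    )
                seen[key] = set_id

    @property
    def set_ids(self) -> list[str]:
        return [sid for sid, _ in self.sets]

    def probes_for(self, set_id: str, platform: str) -> list[str]:
        for sid, members in self.sets:
            if sid == set_id:
                return [probe for plat, probe in members if plat == platform]
        raise KeyError(set_id)


def aggregate_ortholog_row(group_values) -> float:
    """Median of the per-probe group averages within one ortholog set."""
    values = np.asarray(
        [v for v in np.atleast_1d(np.asarray(group_values, dtype=float)) if not np.isnan(v)]
    )
    if values.size == 0:
        raise ValidationError("no contributing probe value for this cell")
    return float(np.median(values))


def build_ortho_table(
    group_tables: dict[str, pd.DataFrame],
    group_platforms: dict[str, str],
    ortho_map: OrthologMap,
) -> pd.DataFrame:
    """Ortholog-set x group table of median-of-averages values.

    ``group_tables`` maps platform -> probes x groups table of group values
    (log2 by default); ``group_platforms`` maps each group column to its
    platform. Requires groups from at least 2 platforms. Rows with no data
    in any group are dropped; empty cells are NaN.
    """
    platforms = set(group_platforms.values())
    if len(platforms) < 2:
        raise ValidationError(
            "orthologous mode needs groups from >= 2 platforms "
            f"(got {sorted(platforms)})"
        )
    for g, plat in group_platforms.items():
        if plat not in group_tables:
            raise ValidationError(f"group {g!r}: no group table for platform {plat!r}")
        if g not in group_tables[plat].columns:
            raise ValidationError(f"group {g!r} missing from its platform table")

    rows = {}
    for set_id, members in ortho_map.sets:
        cells = {}
        any_value = False
        for group, platform in group_platforms.items():
            table = group_tables[platform]
            probes = [p for plat, p in members if plat == platform and p in table.index]
            if probes:
                cells[group] = aggregate_ortholog_row(table.loc[probes, group].to_numpy())
                any_value = True
            else:
                cells[group] = np.nan
        if any_value:
            rows[set_id] = cells
    if not rows:
        raise ValidationError("no ortholog set has data in any selected group")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out = out[list(group_platforms)]
    out.index.name = "ortholog_set"
    return out
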