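"""Data model for expression matrices, sample metadata and sample groups.

Conventions implemented here:

* per-sample median normalization (divide each column by its median);
* fold change = treated intensity / arithmetic mean of the matched control
  group's intensities, stored pre-log;
* group value = log2 of the arithmetic *mean* of the group's fold values
  (mean first, log2 afterwards — never the mean of per-sample logs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DOSE_LEVELS = ("Control", "Low", "Middle", "High")
TEST_TYPES = ("in_vivo", "in_vitro")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation in the upload dialect.

    ``control_group_key`` names the matched vehicle-control group; it must
    resolve (within a dataset) to at least one sample whose ``dose_level``
    is ``Control``.
    """

    sample_id: str
    compound: str
    dose_level: str
    exposure_time: str
    organ: str
    species: str
    platform: str
    test_type: str
    control_group_key: str

    def __post_init__(self):
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.test_type not in TEST_TYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: test_type must be one of "
                f"{TEST_TYPES}, got {self.test_type!r}"
            )


class ExpressionDataset:
    """A probes x samples matrix of positive normalized intensities joined
    to per-sample metadata."""

    def __init__(
        self,
        probes: Sequence[str],
        samples: Sequence[SampleMeta],
        intensities: np.ndarray,
    ):
        self.probes = list(probes)
        self.samples = list(samples)
        self.intensities = np.asarray(intensities, dtype=float)
        self._validate()
        self._probe_index = {p: i for i, p in enumerate(self.probes)}
        self._sample_index = {s.sample_id: j for j, s in enumerate(self.samples)}

    def _validate(self) -> None:
        if len(set(self.probes)) != len(self.probes):
            seen, dups = set(), []
            for p in self.probes:
                if p in seen:
                    dups.append(p)
                seen.add(p)
            raise ValidationError(f"duplicate probe IDs: {sorted(set(dups))}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if self.intensities.shape != (len(self.probes), len(self.samples)):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not "
                f"match {len(self.probes)} probes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.intensities)):
            i, j = np.argwhere(~np.isfinite(self.intensities))[0]
            raise ValidationError(
                f"non-finite intensity at probe {self.probes[i]!r}, "
                f"sample {self.samples[j].sample_id!r}"
            )
        if np.any(self.intensities <= 0):
            i, j = np.argwhere(self.intensities <= 0)[0]
            raise ValidationError(
                f"non-positive intensity at probe {self.probes[i]!r}, "
                f"sample {self.samples[j].sample_id!r}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def probe_loc(self, probe: str) -> int:
        return self._probe_index[probe]

    def sample_loc(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def meta(self, sample_id: str) -> SampleMeta:
        return self.samples[self._sample_index[sample_id]]

    def columns(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Probes x len(sample_ids) view of the intensity matrix."""
        idx = [self._sample_index[s] for s in sample_ids]
        return self.intensities[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.probes, columns=self.sample_ids)

    def control_samples(self, control_group_key: str) -> list[str]:
        """Sample IDs of the Control-dose samples for a control group key."""
        return [
            s.sample_id
            for s in self.samples
            if s.control_group_key == control_group_key and s.dose_level == "Control"
        ]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionDataset)
            and self.probes == other.probes
            and self.samples == other.samples
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(frozen=True)
class SampleGroup:
    """A named set of samples sharing factor levels, with matched controls."""

    name: str
    sample_ids: tuple[str, ...]
    factors: Mapping[str, str] = field(default_factory=dict)
    control_sample_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.name:
            raise ValidationError("group name must be non-empty")
        if not self.sample_ids:
            raise ValidationError(f"group {self.name!r}: sample_ids must be non-empty")
        overlap = set(self.sample_ids) & set(self.control_sample_ids)
        if overlap:
            raise ValidationError(
                f"group {self.name!r}: samples also listed as controls: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class FoldMatrix:
    """Per-sample fold values (ratio to matched control mean), pre-log."""

    probes: tuple[str, ...]
    sample_ids: tuple[str, ...]
    folds: np.ndarray

    def __post_init__(self):
        if self.folds.shape != (len(self.probes), len(self.sample_ids)):
            raise ValidationError("fold matrix shape mismatch")
        if np.any(self.folds <= 0):
            raise ValidationError("fold values must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds, index=list(self.probes), columns=list(self.sample_ids))


# -- operations ------------------------------------------------------------


def median_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Divide every sample column by that column's median.

    Even-length columns use the standard median convention (mean of the two
    middle order statistics). Output columns therefore have median 1.
    """
    # constructor already rejects non-positive values with probe/sample names
    medians = np.median(dataset.intensities, axis=0)
    out = dataset.intensities / medians[np.newaxis, :]
    return ExpressionDataset(dataset.probes, dataset.samples, out)


def compute_fold(sample_values: np.ndarray, control_values: np.ndarray) -> np.ndarray:
    """Fold change per probe: sample value / mean of the control columns.

    ``control_values`` is a probes x n_controls matrix.
    """
    sample_values = np.asarray(sample_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if control_values.ndim != 2 or control_values.shape[1] == 0:
        raise ValidationError("control set must be a non-empty probes x samples matrix")
    if control_values.shape[0] != sample_values.shape[0]:
        raise ValidationError(
            f"probe index mismatch: {sample_values.shape[0]} sample values vs "
            f"{control_values.shape[0]} control rows"
        )
    return sample_values / control_values.mean(axis=1)


def group_log2_value(fold_values: np.ndarray) -> float:
    """log2 of the arithmetic mean of fold values (mean first, then log2)."""
    fold_values = np.asarray(fold_values, dtype=float)
    if fold_values.size == 0:
        raise ValidationError("cannot compute a group value over zero samples")
    if np.any(fold_values <= 0):
        raise ValidationError("fold values must be strictly positive")
    return float(np.log2(fold_values.mean()))


def group_fold_columns(dataset: ExpressionDataset, group: SampleGroup) -> np.ndarray:
    """Per-sample fold values for a group: probes x |group| matrix."""
    if not group.control_sample_ids:
        raise ValidationError(f"group {group.name!r} has no control samples")
    missing = [
        s
        for s in list(group.sample_ids) + list(group.control_sample_ids)
        if s not in dataset._sample_index
    ]
    if missing:
        raise ValidationError(f"group {group.name!r}: unknown sample IDs: {sorted(missing)}")
    controls = dataset.columns(group.control_sample_ids)
    treated = dataset.columns(group.sample_ids)
    return treated / controls.mean(axis=1, keepdims=True)


def build_group_matrix(
    dataset: ExpressionDataset,
    groups: Sequence[SampleGroup],
    mode: str = "log2_fold",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Probes x groups table of group values plus per-group sample counts.

    ``mode='log2_fold'`` computes log2(mean fold vs matched controls);
    ``mode='absolute'`` computes the plain mean of intensities.
    """
    if mode not in ("log2_fold", "absolute"):
        raise ValidationError(f"unknown display mode {mode!r}")
    columns = {}
    counts = {}
    for g in groups:
        if mode == "absolute":
            missing = [s for s in g.sample_ids if s not in dataset._sample_index]
            if missing:
                raise ValidationError(f"group {g.name!r}: unknown sample IDs: {sorted(missing)}")
            columns[g.name] = dataset.columns(g.sample_ids).mean(axis=1)
        else:
            folds = group_fold_columns(dataset, g)
            columns[g.name] = np.log2(folds.mean(axis=1))
        counts[g.name] = len(g.sample_ids)
    table = pd.DataFrame(columns, index=dataset.probes)
    table.index.name = "probe_id"
    return table, counts


def build_fold_matrix(dataset: ExpressionDataset, sample_ids: Sequence[str] | None = None) -> FoldMatrix:
    """Per-sample folds against each sample's matched control-group mean.

    Control samples themselves are folded against their own group mean.
    """
    if sample_ids is None:
        sample_ids = dataset.sample_ids
    folds = np.empty((dataset.n_probes, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        meta = dataset.meta(sid)
        ctrl_ids = dataset.control_samples(meta.control_group_key)
        if not ctrl_ids:
            raise ValidationError(
                f"sample {sid!r}: control group key {meta.control_group_key!r} "
                "resolves to no Control-dose samples"
            )
        controls = dataset.columns(ctrl_ids)
        folds[:, j] = compute_fold(dataset.intensities[:, dataset.sample_loc(sid)], controls)
    return FoldMatrix(tuple(dataset.probes), tuple(sample_ids), folds)


def group_from_factors(
    dataset: ExpressionDataset,
    name: str,
    compound: str,
    dose_level: str,
    exposure_time: str | None = None,
    **extra_factors: str,
) -> SampleGroup:
    """Build a SampleGroup by factor matching, with matched controls
    resolved through the samples' control group keys."""
    members = []
    for s in dataset.samples:
        if s.compound != compound or s.dose_level != dose_level:
            continue
        if exposure_time is not None and s.exposure_time != exposure_time:
            continue
        if any(getattr(s, k) != v for k, v in extra_factors.items()):
            continue
        members.append(s)
    if not members:
        raise ValidationError(
            f"no samples match compound={compound!r} dose={dose_level!r} "
            f"time={exposure_time!r}"
        )
    control_ids: list[str] = []
    for key in sorted({m.control_group_key for m in members}):
        control_ids.extend(dataset.control_samples(key))
    factors = {"compound": compound, "dose_level": dose_level}
    if exposure_time is not None:
        factors["exposure_time"] = exposure_time
    factors.update(extra_factors)
    member_ids = tuple(m.sample_id for m in members)
    control_ids = tuple(c for c in control_ids if c not in member_ids)
    return SampleGroup(name=name, sample_ids=member_ids, factors=factors, control_sample_ids=control_ids)
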