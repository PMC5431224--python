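"""Synthetic TG-GATEs-like dataset generator with planted ground truth.

Intensities are log-normal: log2(intensity) = probe baseline + planted
log2 effect + noise. Each (compound, exposure time) has a matched
Control-dose group of the same replicate count, keyed through
``control_group_key``. Everything is driven by a single mandatory seed so
generated files are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ExpressionDataset, SampleMeta
from .enrichment import AnnotationCollection
from .errors import ValidationError

NOISE_MODELS = ("gaussian", "student_t")


@dataclass(frozen=True)
class Effect:
    """A planted log2 shift on one probe block at one condition."""

    compound: str
    dose_level: str
    time_point: str
    block: str
    log2_effect: float


@dataclass(frozen=True)
class SimConfig:
    n_probes: int = 500
    compounds: tuple[str, ...] = ("compound_A", "compound_B")
    dose_levels: tuple[str, ...] = ("Low", "Middle", "High")
    time_points: tuple[str, ...] = ("4 day", "8 day")
    replicates: int = 3
    organ: str = "liver"
    species: str = "rat"
    platform: str = "array-230-2"
    test_type: str = "in_vivo"
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    noise_sd: float = 0.1
    noise_model: str = "gaussian"
    student_t_df: float = 4.0
    probe_blocks: dict[str, tuple[int, ...]] = field(default_factory=dict)
    effects: tuple[Effect, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_probes < 1:
            raise ValidationError("n_probes must be >= 1")
        if self.replicates < 2:
            raise ValidationError("replicates must be >= 2 for test modules")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if "Control" in self.dose_levels:
            raise ValidationError(
                "dose_levels lists treated doses only; controls are generated "
                "automatically per (compound, time)"
            )
        for name, idx in self.probe_blocks.items():
            bad = [i for i in idx if not (0 <= i < self.n_probes)]
            if bad:
                raise ValidationError(f"block {name!r}: probe indices out of range: {bad}")
        for e in self.effects:
            if e.block not in self.probe_blocks:
                raise ValidationError(f"effect references unknown block {e.block!r}")
            if e.compound not in self.compounds:
                raise ValidationError(f"effect references unknown compound {e.compound!r}")
            if e.dose_level not in self.dose_levels:
                raise ValidationError(f"effect references unknown dose {e.dose_level!r}")
            if e.time_point not in self.time_points:
                raise ValidationError(f"effect references unknown time {e.time_point!r}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth planted into a generated dataset."""

    #: "compound|dose|time" -> probe IDs with a nonzero planted effect there
    deg_sets: dict[str, tuple[str, ...]]
    #: probe ID -> block name, for probes in any block
    block_labels: dict[str, str]
    #: category IDs planted as enriched (filled by generate_collection)
    enriched_categories: tuple[str, ...] = ()
    #: compound planted as the strongest downregulator, if any
    top_compound: str | None = None


def _probe_id(i: int) -> str:
    return f"P{i + 1:05d}"


def _slug(text: str) -> str:
    return text.replace(" ", "")


def generate_dataset(config: SimConfig) -> tuple[ExpressionDataset, SimTruth]:
    """Generate a dataset plus its planted truth, deterministically."""
    rng = np.random.default_rng(config.seed)
    probes = [_probe_id(i) for i in range(config.n_probes)]
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_probes)

    effect_lookup: dict[tuple[str, str, str], np.ndarray] = {}
    for e in config.effects:
        key = (e.compound, e.dose_level, e.time_point)
        vec = effect_lookup.setdefault(key, np.zeros(config.n_probes))
        vec[list(config.probe_blocks[e.block])] += e.log2_effect

    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []

    def noise() -> np.ndarray:
        if config.noise_sd == 0:
            return np.zeros(config.n_probes)
        if config.noise_model == "gaussian":
            return rng.normal(0.0, config.noise_sd, config.n_probes)
        draw = rng.standard_t(config.student_t_df, config.n_probes)
        scale = np.sqrt(config.student_t_df / (config.student_t_df - 2))
        return config.noise_sd * draw / scale

    for compound in config.compounds:
        for time in config.time_points:
            key = f"{compound}|{config.organ}|{time}"
            for dose in ("Control",) + tuple(config.dose_levels):
                effect = effect_lookup.get((compound, dose, time), None)
                for rep in range(1, config.replicates + 1):
                    sid = f"{compound}_{_slug(dose)}_{_slug(time)}_r{rep}"
                    samples.append(
                        SampleMeta(
                            sample_id=sid,
                            compound=compound,
                            dose_level=dose,
                            exposure_time=time,
                            organ=config.organ,
                            species=config.species,
                            platform=config.platform,
                            test_type=config.test_type,
                            control_group_key=key,
                        )
                    )
                    log2 = baseline + noise()
                    if effect is not None:
                        log2 = log2 + effect
                    columns.append(np.power(2.0, log2))

    intensities = np.column_stack(columns)
    dataset = ExpressionDataset(probes, samples, intensities)

    deg_sets = {
        f"{c}|{d}|{t}": tuple(probes[i] for i in np.nonzero(vec)[0])
        for (c, d, t), vec in sorted(effect_lookup.items())
    }
    block_labels = {
        probes[i]: name for name, idx in config.probe_blocks.items() for i in idx
    }
    return dataset, SimTruth(deg_sets=deg_sets, block_labels=block_labels)


def generate_collection(
    universe: list[str],
    planted_members: list[str],
    n_categories: int = 20,
    category_size: int = 30,
    overlap_rate: float = 1.0,
    planted_id: str = "CAT_PLANTED",
    feature_type: str = "pathway",
    seed: int = 0,
) -> tuple[AnnotationCollection, SimTruth]:
    """GMT-style collection with one planted-enriched category.

    The planted category draws ``round(category_size * overlap_rate)``
    members from ``planted_members`` and the rest from the remaining
    universe; the other categories are uniform draws from the universe.
    """
    rng = np.random.default_rng(seed)
    if category_size > len(universe):
        raise ValidationError("category size exceeds universe size")
    n_overlap = int(round(category_size * overlap_rate))
    planted_pool = [g for g in planted_members if g in set(universe)]
    if n_overlap > len(planted_pool):
        raise ValidationError(
            f"cannot plant overlap {n_overlap} from {len(planted_pool)} available genes"
        )
    rest_pool = [g for g in universe if g not in set(planted_members)]
    if category_size - n_overlap > len(rest_pool):
        raise ValidationError("not enough non-planted genes to fill the planted category")

    categories: dict[str, tuple[str, tuple[str, ...]]] = {}
    chosen = list(rng.choice(planted_pool, size=n_overlap, replace=False))
    chosen += list(rng.choice(rest_pool, size=category_size - n_overlap, replace=False))
    categories[planted_id] = ("planted enriched category", tuple(sorted(chosen)))
    for i in range(n_categories - 1):
        members = rng.choice(universe, size=category_size, replace=False)
        categories[f"CAT_{i + 1:03d}"] = (f"background category {i + 1}", tuple(sorted(members)))

    collection = AnnotationCollection(
        name="synthetic", feature_type=feature_type, categories=categories
    )
    truth = SimTruth(deg_sets={}, block_labels={}, enriched_categories=(planted_id,))
    return collection, truth


# -- ready-made scenarios ---------------------------------------------------


def deg_recovery_config(seed: int = 0, n_probes: int = 2000, n_deg: int = 100) -> SimConfig:
    """One compound, one condition, a planted block of strong (+2 log2)
    differential expression; sized for filter sensitivity/FDR checks."""
    return SimConfig(
        n_probes=n_probes,
        compounds=("compound_A",),
        dose_levels=("Middle",),
        time_points=("4 day",),
        replicates=3,
        noise_sd=0.1,
        probe_blocks={"deg": tuple(range(n_deg))},
        effects=(Effect("compound_A", "Middle", "4 day", "deg", 2.0),),
        seed=seed,
    )


def three_cluster_config(
    seed: int = 0, block_size: int = 30, null_compounds: int = 1
) -> SimConfig:
    """Three probe blocks with mutually distinct time profiles over four
    time points, for clustering-recovery checks (well separated).

    ``null_compounds`` extra no-effect compounds make the scenario usable
    for ranking stages too.
    """
    times = ("4 day", "8 day", "15 day", "29 day")
    n = 3 * block_size
    blocks = {
        "early_up": tuple(range(0, block_size)),
        "late_up": tuple(range(block_size, 2 * block_size)),
        "alternating": tuple(range(2 * block_size, n)),
    }
    patterns = {
        "early_up": (2.0, 2.0, 0.0, 0.0),
        "late_up": (0.0, 0.0, 2.0, 2.0),
        "alternating": (2.0, 0.0, 2.0, 0.0),
    }
    effects = tuple(
        Effect("compound_A", "Middle", t, block, eff)
        for block, pattern in patterns.items()
        for t, eff in zip(times, pattern)
        if eff != 0.0
    )
    compounds = ("compound_A",) + tuple(
        f"compound_null_{i + 1}" for i in range(null_compounds)
    )
    return SimConfig(
        n_probes=n,
        compounds=compounds,
        dose_levels=("Middle",),
        time_points=times,
        replicates=3,
        noise_sd=0.05,
        probe_blocks=blocks,
        effects=effects,
        seed=seed,
    )


def ranking_config(seed: int = 0, n_compounds: int = 10, n_query: int = 40) -> SimConfig:
    """One planted downregulator among null compounds; the planted block is
    halved-or-more at every time point for the planted compound only."""
    compounds = tuple(f"compound_{i + 1:02d}" for i in range(n_compounds))
    planted = compounds[0]
    times = ("4 day", "8 day", "15 day", "29 day")
    blocks = {"query": tuple(range(n_query))}
    effects = tuple(
        Effect(planted, "Middle", t, "query", -1.5) for t in times
    )
    config = SimConfig(
        n_probes=400,
        compounds=compounds,
        dose_levels=("Middle",),
        time_points=times,
        replicates=3,
        noise_sd=0.1,
        probe_blocks=blocks,
        effects=effects,
        seed=seed,
    )
    return config


def planted_top_compound(config: SimConfig) -> str | None:
    """The compound with the most negative total planted effect, if any."""
    totals: dict[str, float] = {}
    for e in config.effects:
        totals[e.compound] = totals.get(e.compound, 0.0) + e.log2_effect * len(
            config.probe_blocks[e.block]
        )
    if not totals:
        return None
    return min(sorted(totals), key=lambda c: totals[c])
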