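"""Declarative analysis pipelines: load (or simulate) a dataset, build the
group table, then run filter / stats-filter / cluster / enrich / rank
stages in the declared order, writing every intermediate gene set with its
provenance.

A pipeline configuration is a plain mapping (usually loaded from YAML)::

    seed: 1
    output_dir: out
    dataset: {metadata: meta.tsv, data: data.tsv}   # or simulate: {...}
    groups:
      - {name: M4, compound: compound_A, dose_level: Middle, exposure_time: 4 day}
    stages:
      - {stage: filter, column: M4, kind: lower_abs, threshold: 1.5}
      - {stage: cluster, method: ward_d2, distance: pearson, cutoff: 4}
      - {stage: enrich, collection: pathways.gmt, per_cluster: true}
      - {stage: stats_filter, test: welch_t, group_a: M4, group_b: M8, threshold: 0.01}
      - {stage: rank, mode: total_downregulation, dose_level: Middle}
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as tio
from .clustering import ClusteringConfig, ClusterPartition, cluster_table
from .core import ExpressionDataset, SampleGroup, build_group_matrix, group_from_factors, median_normalize
from .enrichment import enrich, top_feature_per_cluster
from .errors import StageError, ToxpipeError, ValidationError
from .genesets import ColumnFilter, GeneSet, compute_stat_column, filter_table
from .ranking import RankingQuery, compound_fold_tables, rank_compounds
from .simulate import deg_recovery_config, generate_dataset, ranking_config, three_cluster_config

SCENARIOS = {
    "deg_recovery": deg_recovery_config,
    "three_cluster": three_cluster_config,
    "ranking": ranking_config,
}


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    dataset: Mapping[str, Any] = field(default_factory=dict)
    groups: list[Mapping[str, str]] = field(default_factory=list)
    stages: list[Mapping[str, Any]] = field(default_factory=list)
    normalize: bool = True
    log_level: str = "info"

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        if "output_dir" not in raw:
            raise ValidationError("pipeline config requires output_dir")
        return cls(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            dataset=raw.get("dataset", {}),
            groups=list(raw.get("groups", [])),
            stages=list(raw.get("stages", [])),
            normalize=bool(raw.get("normalize", True)),
            log_level=str(raw.get("log_level", "info")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"pipeline config {path} is not a mapping")
        return cls.from_dict(raw)


@dataclass
class PipelineState:
    dataset: ExpressionDataset
    groups: list[SampleGroup]
    table: pd.DataFrame
    current_set: GeneSet
    partition: ClusterPartition | None = None
    ranking: pd.DataFrame | None = None


class _Log:
    """Line logger to stderr and a run-log file (no timestamps so reruns
    stay byte-identical)."""

    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def __call__(self, message: str) -> None:
        self.lines.append(message)
        print(message, file=sys.stderr)

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _load_dataset(cfg: PipelineConfig, log: _Log) -> ExpressionDataset:
    spec = dict(cfg.dataset)
    if "simulate" in spec:
        sim = dict(spec["simulate"])
        scenario = sim.pop("scenario", "deg_recovery")
        if scenario not in SCENARIOS:
            raise ValidationError(f"unknown simulation scenario {scenario!r}")
        sim.setdefault("seed", cfg.seed)
        dataset, _ = generate_dataset(SCENARIOS[scenario](**sim))
        log(f"simulated dataset: scenario={scenario} "
            f"({dataset.n_probes} probes x {dataset.n_samples} samples)")
        return dataset
    if "metadata" not in spec or "data" not in spec:
        raise ValidationError("dataset spec needs metadata+data paths or a simulate block")
    dataset = tio.read_upload_pair(spec["metadata"], spec["data"])
    log(f"loaded dataset: {dataset.n_probes} probes x {dataset.n_samples} samples")
    return dataset


def _restrict(table: pd.DataFrame, gene_set: GeneSet) -> pd.DataFrame:
    members = [m for m in gene_set.members if m in table.index]
    return table.loc[members]


def run_pipeline(config: PipelineConfig | Mapping[str, Any]) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Any stage error aborts the run with a stage-tagged message.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "run.log")

    try:
        dataset = _load_dataset(config, log)
        if config.normalize:
            dataset = median_normalize(dataset)
            log("median-normalized all sample columns")
        groups = []
        for g in config.groups:
            spec = dict(g)
            name = spec.pop("name")
            groups.append(group_from_factors(dataset, name, **spec))
        if not groups:
            raise ValidationError("pipeline config defines no sample groups")
        table, counts = build_group_matrix(dataset, groups)
        log(f"group table: {table.shape[0]} probes x {table.shape[1]} groups "
            f"(sizes {counts})")
        tio.export_table(table, outdir / "group_table.csv", mode="grouped")
    except ToxpipeError as exc:
        log(f"setup failed: {exc}")
        log.flush()
        raise StageError("setup", str(exc)) from exc

    all_probes = GeneSet(name="all_probes", members=tuple(table.index),
                         provenance="all probes in the group table")
    state = PipelineState(dataset=dataset, groups=groups, table=table,
                          current_set=all_probes)

    for idx, raw_stage in enumerate(config.stages, start=1):
        stage = dict(raw_stage)
        kind = stage.pop("stage", None)
        tag = f"{idx:02d}_{kind}"
        handler = _STAGE_HANDLERS.get(kind)
        if handler is None:
            log.flush()
            raise StageError(str(kind), f"unknown stage kind {kind!r}")
        try:
            handler(state, stage, outdir, tag, log, config)
        except ToxpipeError as exc:
            log(f"stage {tag} failed: {exc}")
            log.flush()
            raise StageError(tag, str(exc)) from exc
    log.flush()
    return outdir


# -- stage handlers ---------------------------------------------------------


def _stage_filter(state, spec, outdir, tag, log, cfg):
    columns = spec.get("columns")
    if columns is None:
        columns = {spec["column"]: {"kind": spec["kind"], "threshold": spec["threshold"]}}
    filters = {
        col: ColumnFilter(kind=f["kind"], threshold=float(f["threshold"]),
                          active=bool(f.get("active", True)))
        for col, f in columns.items()
    }
    sub = _restrict(state.table, state.current_set)
    gene_set = filter_table(sub, filters, name=spec.get("name", tag))
    if not gene_set.members:
        raise ValidationError("filter stage produced an empty gene set")
    tio.write_gene_set(gene_set, outdir / f"{tag}.geneset.txt")
    log(f"stage {tag}: {len(gene_set)} probes pass")
    state.current_set = gene_set


def _stage_stats_filter(state, spec, outdir, tag, log, cfg):
    group_by_name = {g.name: g for g in state.groups}
    for key in ("group_a", "group_b"):
        if spec.get(key) not in group_by_name:
            raise ValidationError(f"unknown group {spec.get(key)!r}")
    column = compute_stat_column(
        state.dataset,
        group_by_name[spec["group_a"]],
        group_by_name[spec["group_b"]],
        test=spec.get("test", "welch_t"),
    )
    threshold = float(spec.get("threshold", 0.01))
    p = column.values.reindex(state.current_set.members)
    keep = tuple(p.index[(p <= threshold).fillna(False)])
    gene_set = GeneSet(
        name=spec.get("name", tag),
        members=keep,
        provenance=(
            f"{column.test} {column.group_a} vs {column.group_b}, "
            f"p <= {threshold:g}"
        ),
    )
    if not gene_set.members:
        raise ValidationError("stats filter produced an empty gene set")
    tio.write_gene_set(gene_set, outdir / f"{tag}.geneset.txt")
    log(f"stage {tag}: {len(gene_set)} probes at p <= {threshold:g}")
    state.current_set = gene_set


def _stage_cluster(state, spec, outdir, tag, log, cfg):
    cluster_cfg = ClusteringConfig(
        method=spec.get("method", "ward_d2"),
        distance=spec.get("distance", "pearson"),
        axis=spec.get("axis", "rows"),
        max_genes=int(spec.get("max_genes", ClusteringConfig().max_genes)),
    )
    sub = _restrict(state.table, state.current_set)
    if sub.empty:
        raise ValidationError("no probes available for clustering (empty gene set)")
    cutoff = spec.get("cutoff")
    result = cluster_table(sub, cluster_cfg, cutoff=None if cutoff is None else float(cutoff))
    if result.partition is not None:
        tio.write_partition(
            result.partition, result.row_dendrogram, cluster_cfg,
            outdir / f"{tag}.partition.tsv", outdir / f"{tag}.partition.json",
        )
        for gs in result.gene_sets:
            tio.write_gene_set(gs, outdir / f"{tag}.{gs.name}.geneset.txt")
        log(f"stage {tag}: {len(result.partition.clusters)} clusters at "
            f"cutoff {float(cutoff):g}")
    else:
        log(f"stage {tag}: dendrogram over {sub.shape[0]} probes (no cutoff)")
    state.partition = result.partition


def _stage_enrich(state, spec, outdir, tag, log, cfg):
    collection = tio.read_gmt(spec["collection"])
    universe = GeneSet(name="universe", members=tuple(state.table.index))
    if spec.get("per_cluster", False):
        if state.partition is None:
            raise ValidationError("per-cluster enrichment needs a preceding cluster stage")
        top = top_feature_per_cluster(state.partition, universe, collection)
        lines = ["cluster\tcategory\tp_raw"]
        for cluster, hit in top.items():
            if hit is None:
                lines.append(f"{cluster}\tnone\t")
            else:
                lines.append(f"{cluster}\t{hit[0]}\t{hit[1]:.12g}")
        (outdir / f"{tag}.top_features.tsv").write_text("\n".join(lines) + "\n")
        for name, members in zip(state.partition.names, state.partition.clusters):
            try:
                table = enrich(GeneSet(name=name, members=members), universe,
                               collection, adjust=spec.get("adjust", "bh"))
            except ValidationError:
                continue
            tio.write_enrichment(table, outdir / f"{tag}.{name}.enrichment.tsv")
        log(f"stage {tag}: per-cluster enrichment over {len(top)} clusters")
    else:
        table = enrich(state.current_set, universe, collection,
                       adjust=spec.get("adjust", "bh"))
        tio.write_enrichment(table, outdir / f"{tag}.enrichment.tsv")
        log(f"stage {tag}: {len(table)} categories tested")


def _stage_rank(state, spec, outdir, tag, log, cfg):
    gene_set = state.current_set
    if "gene_set" in spec:
        gene_set = tio.read_gene_set(spec["gene_set"])
    query = RankingQuery(
        gene_set=gene_set,
        mode=spec.get("mode", "total_downregulation"),
        scope=dict(spec.get("scope", {})),
    )
    tables = compound_fold_tables(
        state.dataset, dose_level=spec.get("dose_level", "Middle"), scope=query.scope
    )
    ranking = rank_compounds(tables, query)
    tio.write_ranking(ranking, outdir / f"{tag}.ranking.tsv")
    log(f"stage {tag}: ranked {len(ranking)} compounds; "
        f"top = {ranking.iloc[0]['compound']}")
    state.ranking = ranking


def _stage_export(state, spec, outdir, tag, log, cfg):
    mode = spec.get("mode", "grouped")
    if mode == "grouped":
        table = _restrict(state.table, state.current_set)
    else:
        from .core import build_fold_matrix

        table = build_fold_matrix(state.dataset).to_frame()
        table = table.loc[[m for m in state.current_set.members if m in table.index]]
    tio.export_table(table, outdir / f"{tag}.{mode}.csv", mode=mode)
    log(f"stage {tag}: exported {mode} table ({table.shape[0]} rows)")


_STAGE_HANDLERS = {
    "filter": _stage_filter,
    "stats_filter": _stage_stats_filter,
    "cluster": _stage_cluster,
    "enrich": _stage_enrich,
    "rank": _stage_rank,
    "export": _stage_export,
}
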