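"""Readers and writers for the on-disk formats.

Inputs are TSV by default (delimiter auto-detected, overridable); exports
are CSV. Gene sets persist as one-ID-per-line text with ``#`` headers;
multi-set interchange uses GMT. Floats are written in their shortest
round-tripping representation, so writer->reader round trips are exact and
reruns are byte-identical.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterPartition, ClusteringConfig, Dendrogram
from .core import DOSE_LEVELS, ExpressionDataset, SampleMeta
from .enrichment import RESULT_COLUMNS, AnnotationCollection
from .errors import ValidationError
from .genesets import GeneSet
from .ortho import OrthologMap

FLOAT_FORMAT = None  # pandas default: shortest exact float repr

METADATA_COLUMNS = [
    "sample_id",
    "compound",
    "dose_level",
    "exposure_time",
    "organ",
    "species",
    "platform",
    "test_type",
    "control_group",
]


def _detect_sep(path: Path, override: str | None = None) -> str:
    if override is not None:
        return override
    head = Path(path).read_text().splitlines()[0] if Path(path).stat().st_size else ""
    return "\t" if "\t" in head or "," not in head else ","


# -- expression + metadata --------------------------------------------------


def read_expression_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Probes x samples matrix; first column probe IDs, header sample IDs."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path, sep: str | None = None) -> list[SampleMeta]:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata file {path.name}: missing required columns {missing}")
    ids = df["sample_id"].tolist()
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValidationError(f"metadata file {path.name}: duplicate sample IDs {dups}")
    unknown_doses = sorted(set(df["dose_level"]) - set(DOSE_LEVELS))
    if unknown_doses:
        warnings.warn(
            f"metadata file {path.name}: non-standard dose levels accepted as "
            f"free text: {unknown_doses}"
        )
    return [
        SampleMeta(
            sample_id=row["sample_id"],
            compound=row["compound"],
            dose_level=row["dose_level"],
            exposure_time=row["exposure_time"],
            organ=row["organ"],
            species=row["species"],
            platform=row["platform"],
            test_type=row["test_type"],
            control_group_key=row["control_group"],
        )
        for row in df.to_dict(orient="records")
    ]


def write_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "compound": s.compound,
            "dose_level": s.dose_level,
            "exposure_time": s.exposure_time,
            "organ": s.organ,
            "species": s.species,
            "platform": s.platform,
            "test_type": s.test_type,
            "control_group": s.control_group_key,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_upload_pair(
    metadata_path: str | Path, data_path: str | Path, sep: str | None = None
) -> ExpressionDataset:
    """Read a metadata + normalized-data file pair into a validated dataset.

    Validation problems (missing columns, duplicate IDs, samples present in
    only one file) are reported together in one itemized error.
    """
    samples = read_metadata(metadata_path, sep=sep)
    matrix = read_expression_matrix(data_path, sep=sep)
    meta_ids = [s.sample_id for s in samples]
    data_ids = [str(c) for c in matrix.columns]
    problems = []
    only_meta = [s for s in meta_ids if s not in set(data_ids)]
    only_data = [s for s in data_ids if s not in set(meta_ids)]
    if only_meta:
        problems.append(f"samples only in metadata: {only_meta}")
    if only_data:
        problems.append(f"samples only in data file: {only_data}")
    if problems:
        raise ValidationError(
            "metadata/data sample mismatch: " + "; ".join(problems)
        )
    matrix = matrix[meta_ids]  # align column order to the metadata
    return ExpressionDataset(list(matrix.index), samples, matrix.to_numpy(dtype=float))


def write_dataset(
    dataset: ExpressionDataset, metadata_path: str | Path, data_path: str | Path
) -> None:
    write_metadata(dataset.samples, metadata_path)
    write_expression_matrix(dataset.to_frame(), data_path)


# -- gene sets and GMT ------------------------------------------------------


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    lines = [f"# name: {gene_set.name}"]
    if gene_set.provenance:
        lines.append(f"# provenance: {gene_set.provenance}")
    lines.extend(gene_set.members)
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_set(path: str | Path) -> GeneSet:
    path = Path(path)
    name = path.stem
    provenance = ""
    members = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("name:"):
                name = body[5:].strip()
            elif body.lower().startswith("provenance:"):
                provenance = body[11:].strip()
            continue
        members.append(line)
    return GeneSet(name=name, members=tuple(members), provenance=provenance)


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for gs in sets:
            desc = gs.provenance or "na"
            fh.write("\t".join([gs.name, desc, *gs.members]) + "\n")


def read_gmt(path: str | Path, name: str | None = None, feature_type: str = "other") -> AnnotationCollection:
    path = Path(path)
    categories: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path.name}:{lineno}: GMT lines need name, description and >= 1 member"
            )
        cid, desc, members = parts[0], parts[1], tuple(dict.fromkeys(parts[2:]))
        if cid in categories:
            raise ValidationError(f"{path.name}: duplicate category {cid!r}")
        categories[cid] = (desc, members)
    return AnnotationCollection(
        name=name or path.stem, feature_type=feature_type, categories=categories
    )


def read_gmt_gene_sets(path: str | Path) -> list[GeneSet]:
    coll = read_gmt(path)
    return [
        GeneSet(name=cid, members=members, provenance=desc)
        for cid, (desc, members) in coll.categories.items()
    ]


# -- clustering outputs -----------------------------------------------------


def write_partition(
    partition: ClusterPartition,
    dendrogram: Dendrogram,
    config: ClusteringConfig,
    tsv_path: str | Path,
    json_path: str | Path,
) -> None:
    """Partition TSV (probe_id -> cluster) plus a JSON sidecar with the
    merge list at full double precision."""
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["probe_id", "cluster_id"])
        for name, members in zip(partition.names, partition.clusters):
            for probe in members:
                writer.writerow([probe, name])
    sidecar = {
        "cutoff": partition.cutoff,
        "config": {
            "method": config.method,
            "distance": config.distance,
            "axis": config.axis,
            "max_genes": config.max_genes,
        },
        "n_leaves": dendrogram.n_leaves,
        "leaf_labels": list(dendrogram.leaf_labels),
        "merges": [[left, right, height] for left, right, height in dendrogram.merges],
        "clusters": {
            name: list(members)
            for name, members in zip(partition.names, partition.clusters)
        },
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=1) + "\n")


def read_partition(tsv_path: str | Path) -> dict[str, str]:
    labels = {}
    with open(tsv_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ["probe_id", "cluster_id"]:
            raise ValidationError(f"unexpected partition header: {header}")
        for probe, cluster in reader:
            labels[probe] = cluster
    return labels


# -- ortholog maps ----------------------------------------------------------


def read_ortholog_map(path: str | Path, sep: str | None = None) -> OrthologMap:
    """Tab-separated set_id, platform, probe_id (header optional)."""
    path = Path(path)
    sets: dict[str, list[tuple[str, str]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split(sep or "\t")
        if lineno == 1 and parts[:3] == ["set_id", "platform", "probe_id"]:
            continue
        if len(parts) != 3:
            raise ValidationError(
                f"{path.name}:{lineno}: expected 3 columns (set_id, platform, probe_id)"
            )
        set_id, platform, probe = parts
        sets.setdefault(set_id, []).append((platform, probe))
    return OrthologMap(
        sets=tuple((sid, tuple(members)) for sid, members in sets.items()),
        provenance=f"loaded from {path.name}",
    )


def write_ortholog_map(ortho_map: OrthologMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["set_id", "platform", "probe_id"])
        for set_id, members in ortho_map.sets:
            for platform, probe in members:
                writer.writerow([set_id, platform, probe])


# -- tabular exports --------------------------------------------------------


def export_table(table: pd.DataFrame, path: str | Path, mode: str = "grouped") -> None:
    """CSV export: ``grouped`` = probes x groups log2 values; ``individual``
    = probes x samples pre-log fold values."""
    if mode not in ("grouped", "individual"):
        raise ValidationError(f"unknown export mode {mode!r}")
    out = table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, float_format=FLOAT_FORMAT)


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    table[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_ranking(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
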