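"""TSV / GMT readers and writers, plus run manifests.

All tables are UTF-8, tab-separated, '.' decimal. The count table has
``gene_id`` as its first column and one column per sample; the annotation
table has columns ``sample_id``, ``group``, ``condition``; gene sets use
the de-facto GMT standard (set name, description, then member IDs, one set
per line). Writers and readers round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from degvenn.datatypes import CountMatrix, GeneSet, GeneSetCollection, GroundTruth
from degvenn.errors import ValidationError
from degvenn.simulate import SimulationConfig


def read_count_matrix(counts_path, annotation_path) -> CountMatrix:
    """Read counts + annotation TSVs into a validated :class:`CountMatrix`."""
    counts = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if counts.columns[0] != "gene_id":
        raise ValidationError(
            f"{counts_path}: first column must be 'gene_id', got {counts.columns[0]!r}"
        )
    counts = counts.set_index("gene_id")
    for col in counts.columns:
        bad = counts[col][~counts[col].apply(lambda v: float(v).is_integer())]
        if len(bad):
            row = bad.index[0]
            raise ValidationError(
                f"{counts_path}: non-integer count {bad.iloc[0]!r} at gene "
                f"{row!r}, sample {col!r}"
            )
    counts = counts.astype("int64")
    annotation = read_annotation(annotation_path)
    missing = set(annotation.index) ^ set(counts.columns)
    if missing:
        raise ValidationError(
            f"samples differ between {counts_path} and {annotation_path}: "
            f"{sorted(missing)}"
        )
    return CountMatrix(counts=counts, annotation=annotation)


def read_annotation(path) -> pd.DataFrame:
    annotation = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "condition"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValidationError(f"{path}: annotation lacks columns {sorted(missing)}")
    if annotation["sample_id"].duplicated().any():
        dupes = annotation["sample_id"][annotation["sample_id"].duplicated()]
        raise ValidationError(f"{path}: duplicate sample ids {sorted(set(dupes))}")
    return annotation.set_index("sample_id")


def write_count_matrix(cm: CountMatrix, counts_path, annotation_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.annotation.rename_axis("sample_id").to_csv(annotation_path, sep="\t")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file; malformed lines are reported with their line number."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and at "
                    f"least one member, got {len(fields)} fields"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            try:
                sets.append(GeneSet(name, description, tuple(members)))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def write_truth(truth: GroundTruth, genes_path, size_factors_path) -> None:
    truth.genes.rename_axis("gene_id").to_csv(genes_path, sep="\t")
    truth.size_factors.rename_axis("sample_id").to_frame().to_csv(
        size_factors_path, sep="\t"
    )


def read_truth(genes_path, size_factors_path) -> GroundTruth:
    genes = pd.read_csv(genes_path, sep="\t", index_col="gene_id")
    genes["is_de_shared"] = genes["is_de_shared"].astype(bool)
    genes["has_interaction"] = genes["has_interaction"].astype(bool)
    sf = pd.read_csv(size_factors_path, sep="\t", index_col="sample_id")[
        "size_factor"
    ]
    return GroundTruth(genes=genes, size_factors=sf)


def write_results_table(table: pd.DataFrame, path) -> None:
    table.rename_axis("gene_id").to_csv(path, sep="\t")


def write_manifest(
    path,
    *,
    seed: int,
    config: SimulationConfig | None = None,
    inputs: dict | None = None,
    extra: dict | None = None,
) -> None:
    """JSON manifest naming inputs, resolved configuration and seed."""
    from degvenn import __version__

    payload: dict = {"package_version": __version__, "seed": seed}
    if config is not None:
        cfg = asdict(config)
        payload["config"] = cfg
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
        payload["config_sha256"] = digest
    if inputs:
        payload["inputs"] = {k: str(v) for k, v in inputs.items()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
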