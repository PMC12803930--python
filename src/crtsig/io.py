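"""Readers and writers for the pipeline's TSV/JSON interchange formats.

Matrices are TSV with the gene (or probe) id in the first column and sample
(or segment) ids in the header; annotations are TSV keyed by sample or
segment id. The harmonization transform record travels as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import ANNOTATION_COLUMNS, ExpressionCohort, HarmonizedMatrix
from .errors import DataError
from .spatial_qc import SpatialExperiment


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataError(f"{path}: empty matrix")
    return df


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: annotation lacks columns {missing}")
    df["trg"] = df["trg"].astype("Int64")
    return df


def write_annotation_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_cohort(matrix_path, annot_path, name: str | None = None) -> ExpressionCohort:
    expr = read_matrix_tsv(matrix_path)
    samples = read_annotation_tsv(annot_path)
    samples = samples.loc[samples.index.intersection(expr.columns)]
    expr = expr.loc[:, samples.index]
    if name is None:
        name = str(samples["batch"].iloc[0])
    return ExpressionCohort(name=name, expr=expr, samples=samples)


def write_harmonized(hm: HarmonizedMatrix, matrix_path, annot_path, transform_path) -> None:
    write_matrix_tsv(hm.matrix, matrix_path)
    write_annotation_tsv(hm.samples, annot_path)
    record = {
        "provenance": hm.provenance,
        "dropped_genes": hm.dropped_genes,
        "transform": hm.transform.to_dict(orient="records"),
    }
    Path(transform_path).write_text(json.dumps(record, indent=1))


def read_harmonized(matrix_path, annot_path, transform_path=None) -> HarmonizedMatrix:
    matrix = read_matrix_tsv(matrix_path)
    samples = read_annotation_tsv(annot_path)
    samples = samples.loc[matrix.columns]
    if transform_path is not None and Path(transform_path).exists():
        rec = json.loads(Path(transform_path).read_text())
        transform = pd.DataFrame(rec["transform"])
        provenance = rec.get("provenance", [])
        dropped = rec.get("dropped_genes", {})
    else:
        transform = pd.DataFrame(columns=["dataset", "gene", "mean", "sd"])
        provenance, dropped = [], {}
    return HarmonizedMatrix(
        matrix=matrix, samples=samples, transform=transform,
        provenance=provenance, dropped_genes=dropped,
    )


def write_gene_list(genes: list[str], path) -> None:
    pd.DataFrame({"gene_id": genes}).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise DataError(f"{path}: expected a gene_id column")
    return df["gene_id"].astype(str).tolist()


def write_spatial(exp: SpatialExperiment, counts_path, probes_path, segments_path) -> None:
    write_matrix_tsv(exp.counts, counts_path, index_label="probe_id")
    exp.probes.to_csv(probes_path, sep="\t", index_label="probe_id")
    exp.segments.to_csv(segments_path, sep="\t", index_label="segment_id")


def read_spatial(counts_path, probes_path, segments_path) -> SpatialExperiment:
    counts = read_matrix_tsv(counts_path)
    probes = pd.read_csv(probes_path, sep="\t", index_col=0)
    if "is_negative" not in probes.columns or "target" not in probes.columns:
        raise DataError(f"{probes_path}: need target and is_negative columns")
    probes["is_negative"] = probes["is_negative"].astype(bool)
    segments = pd.read_csv(segments_path, sep="\t", index_col=0)
    return SpatialExperiment(counts=counts, probes=probes, segments=segments)
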