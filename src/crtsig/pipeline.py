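"""End-to-end orchestration of simulate -> harmonize -> select -> evaluate
(and the spatial chain) from a single configuration mapping, with a
machine-readable run manifest.

A single global seed fans out to per-stage seeds through a counter scheme:
stage i receives ``SeedSequence([seed, i])``, so each stage is independently
reproducible regardless of which other stages run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .cv_dea import run_cv_dea, select_signature_genes
from .errors import ConfigError, DataError
from .harmonize import harmonize_cohorts
from .signature_ml import cross_validate_signature
from .spatial_model import consensus_marker_analysis, make_pseudobulk
from .spatial_qc import run_spatial_qc
from .synthetic import BulkSimConfig, SpatialSimConfig, generate_bulk_cohorts, generate_spatial_cohort

STAGES = (
    "simulate",
    "harmonize",
    "cvdea",
    "evaluate",
    "simulate_spatial",
    "spatial_qc",
    "spatial_fit",
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([seed, stage index])."""
    return int(np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dataclass_config(cls, params: dict, seed: int):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(params) - fields
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    params = dict(params)
    params.setdefault("seed", seed)
    for key in ("planted_genes", "planted_tumor_genes", "planted_stroma_genes",
                "planted_opposing_genes"):
        if key in params and params[key] is not None:
            params[key] = tuple((int(g), float(e)) for g, e in params[key])
    return cls(**params)


def _stage_simulate(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    sim = _dataclass_config(BulkSimConfig, cfg.get("simulate", {}), seed)
    cohorts, truth = generate_bulk_cohorts(sim)
    outputs = []
    annots = []
    for c in cohorts:
        p = outdir / f"expr_{c.name}.tsv"
        io.write_matrix_tsv(c.expr, p)
        outputs.append(p)
        annots.append(c.samples)
    annot_path = outdir / "annotations.tsv"
    io.write_annotation_tsv(pd.concat(annots), annot_path)
    truth_path = outdir / "bulk_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return outputs + [annot_path, truth_path]


def _stage_harmonize(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    annot = io.read_annotation_tsv(outdir / "annotations.tsv")
    cohorts = []
    for batch in sorted(annot["batch"].unique()):
        sub = annot[annot["batch"] == batch]
        expr = io.read_matrix_tsv(outdir / f"expr_{batch}.tsv").loc[:, sub.index]
        from .cohort import ExpressionCohort

        cohorts.append(ExpressionCohort(name=str(batch), expr=expr, samples=sub))
    force = bool(cfg.get("harmonize", {}).get("force_log2_intensity", True))
    hm = harmonize_cohorts(cohorts, force_log2_intensity=force)
    paths = [outdir / "harmonized.tsv", outdir / "harmonized_annot.tsv",
             outdir / "transform.json"]
    io.write_harmonized(hm, *paths)
    return paths


def _stage_cvdea(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    params = cfg.get("cvdea", {})
    hm = io.read_harmonized(outdir / "harmonized.tsv", outdir / "harmonized_annot.tsv",
                            outdir / "transform.json")
    n_folds = int(params.get("folds", 10))
    keep = int(params.get("keep", 8))
    thr = float(params.get("mean_p", 0.05))
    subset = params.get("subset_datasets")
    res_all = run_cv_dea(hm, n_folds=n_folds, keep=keep, seed=seed)
    outputs = [outdir / "cvdea_all.tsv"]
    res_all.table.to_csv(outputs[0], sep="\t", index_label="gene_id")
    if subset:
        res_sub = run_cv_dea(hm, datasets=list(subset), n_folds=n_folds, keep=keep,
                             seed=seed + 1)
        p = outdir / "cvdea_subset.tsv"
        res_sub.table.to_csv(p, sep="\t", index_label="gene_id")
        outputs.append(p)
    else:
        res_sub = res_all
    sig = select_signature_genes(res_all, res_sub, mean_p_threshold=thr,
                                 mode=params.get("mode", "mean"))
    sig_path = outdir / "signature.tsv"
    io.write_gene_list(sig.gene_ids, sig_path)
    outputs.append(sig_path)
    return outputs


def _stage_evaluate(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    params = cfg.get("evaluate", {})
    hm = io.read_harmonized(outdir / "harmonized.tsv", outdir / "harmonized_annot.tsv")
    genes = io.read_gene_list(outdir / "signature.tsv")
    if not genes:
        raise DataError("signature is empty; nothing to evaluate")
    from .cohort import NON_RESPONDER, RESPONDER

    mask = hm.samples["response"].isin([RESPONDER, NON_RESPONDER])
    matrix = hm.matrix.loc[:, hm.samples.index[mask]]
    labels = hm.samples.loc[mask, "response"]
    report = {}
    for method in params.get("methods", ["l2_logistic", "random_forest"]):
        ev = cross_validate_signature(
            matrix, genes, labels, method=method,
            n_folds=int(params.get("folds", 5)),
            tune_iters=int(params.get("tune_iters", 20)),
            seed=seed,
        )
        report[method] = {
            "per_fold_auc": ev.per_fold_auc,
            "mean_auc": ev.mean_auc,
            "sd_auc": ev.sd_auc,
            "tuned_params": ev.tuned_params,
        }
    path = outdir / "evaluation.json"
    path.write_text(json.dumps(report, indent=1))
    return [path]


def _stage_simulate_spatial(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    sim = _dataclass_config(SpatialSimConfig, cfg.get("simulate_spatial", {}), seed)
    exp, truth = generate_spatial_cohort(sim)
    paths = [outdir / "spatial_counts.tsv", outdir / "spatial_probes.tsv",
             outdir / "spatial_segments.tsv"]
    io.write_spatial(exp, *paths)
    truth_path = outdir / "spatial_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return paths + [truth_path]


def _stage_spatial_qc(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    exp = io.read_spatial(outdir / "spatial_counts.tsv", outdir / "spatial_probes.tsv",
                          outdir / "spatial_segments.tsv")
    gm, report = run_spatial_qc(exp)
    norm_path = outdir / "spatial_norm.tsv"
    io.write_matrix_tsv(gm.counts, norm_path)
    seg_path = outdir / "spatial_segments_pass.tsv"
    gm.segments.to_csv(seg_path, sep="\t", index_label="segment_id")
    report_path = outdir / "spatial_qc_report.json"
    report_path.write_text(json.dumps(report, indent=1))
    return [norm_path, seg_path, report_path]


def _stage_spatial_fit(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    params = cfg.get("spatial_fit", {})
    counts = io.read_matrix_tsv(outdir / "spatial_norm.tsv")
    meta = pd.read_csv(outdir / "spatial_segments_pass.tsv", sep="\t", index_col=0)
    expr = np.log2(counts + 1.0)
    table = consensus_marker_analysis(
        expr, meta,
        n_runs=int(params.get("bootstrap", 5)),
        q_threshold=float(params.get("q", 0.05)),
        seed=seed,
    )
    fit_path = outdir / "spatial_fits.tsv"
    table.to_csv(fit_path, sep="\t", index_label="gene_id")
    pb, _ = make_pseudobulk(counts, meta)
    pb_path = outdir / "pseudobulk.tsv"
    io.write_matrix_tsv(pb, pb_path)
    return [fit_path, pb_path]


_RUNNERS = {
    "simulate": _stage_simulate,
    "harmonize": _stage_harmonize,
    "cvdea": _stage_cvdea,
    "evaluate": _stage_evaluate,
    "simulate_spatial": _stage_simulate_spatial,
    "spatial_qc": _stage_spatial_qc,
    "spatial_fit": _stage_spatial_fit,
}


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    return cfg


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute the declared stages in order; returns the run manifest.

    The manifest lists every output file with a SHA-256 digest and the
    wall-clock time per stage; deterministic stages reproduce their digests
    when re-run with the same config and seed.
    """
    stages = config.get("stages")
    if not stages:
        raise ConfigError("config must declare a nonempty 'stages' list")
    unknown = [s for s in stages if s not in _RUNNERS]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
    if seed is None:
        seed = int(config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": [],
    }
    for stage in stages:
        t0 = time.perf_counter()
        outputs = _RUNNERS[stage](config, outdir, stage_seed(seed, stage))
        manifest["stages"].append(
            {
                "name": stage,
                "seed": stage_seed(seed, stage),
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": [
                    {"path": p.name, "sha256": _sha256(p)} for p in outputs
                ],
            }
        )
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
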