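"""Cross-platform harmonization of bulk expression cohorts.

Microarray intensity cohorts and RNA-seq count cohorts have incompatible
distributions, and global batch-correction across platform families loses
information. The conservative harmonization implemented here is: log2(x+1) on
raw counts, then per-gene mean centering and standardization within each
source dataset, then column-wise merging on the shared gene set. Additive
gene-wise batch offsets (and multiplicative scale differences) are removed by
construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import PLATFORM_COUNT, PLATFORM_INTENSITY, ExpressionCohort, HarmonizedMatrix
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


def log2p1_transform(cohort: ExpressionCohort, force: bool = False) -> ExpressionCohort:
    """Apply log2(v+1) to every value of count-platform samples.

    Intensity platforms are assumed to arrive already log-scaled by upstream
    processing and are skipped unless ``force`` is set (use it when raw,
    un-logged intensities are supplied, e.g. by the synthetic generator).
    """
    expr = cohort.expr.copy()
    platforms = cohort.samples["platform"]
    take = platforms == PLATFORM_COUNT
    if force:
        take = take | (platforms == PLATFORM_INTENSITY)
    cols = expr.columns[take.to_numpy()]
    if len(cols):
        block = expr[cols].to_numpy(dtype=float)
        if (block < 0).any():
            gi, si = np.argwhere(block < 0)[0]
            raise DataError(
                f"cohort {cohort.name!r}: negative value at gene "
                f"{expr.index[gi]!r}, sample {cols[si]!r}"
            )
        expr[cols] = np.log2(block + 1.0)
    return ExpressionCohort(name=cohort.name, expr=expr, samples=cohort.samples.copy())


def center_and_scale(cohort: ExpressionCohort) -> HarmonizedMatrix:
    """Per gene and per dataset (batch label): subtract the mean, divide by
    the (n-1)-denominator sample SD.

    Genes with zero variance in any dataset are dropped (a constant gene
    carries no signature information) and recorded in ``dropped_genes``.
    The (mean, sd) pairs are retained so held-out samples can be projected
    with :func:`project_samples`.
    """
    batches = cohort.samples["batch"]
    pieces: list[pd.DataFrame] = []
    records: list[pd.DataFrame] = []
    dropped: dict[str, list[str]] = {}
    drop_idx: set[str] = set()
    stats = {}
    for batch, idx in cohort.samples.groupby("batch", sort=True).groups.items():
        if len(idx) < 2:
            raise ConfigError(
                f"dataset {batch!r} has {len(idx)} sample(s); need >=2 to standardize"
            )
        block = cohort.expr.loc[:, idx]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            genes = cohort.expr.index[zero].tolist()
            dropped[str(batch)] = genes
            drop_idx.update(genes)
            logger.warning(
                "dataset %s: dropping %d zero-variance gene(s), e.g. %s",
                batch, len(genes), genes[:3],
            )
        stats[batch] = (idx, mean, sd)
    keep = cohort.expr.index[~cohort.expr.index.isin(drop_idx)]
    for batch, (idx, mean, sd) in stats.items():
        block = cohort.expr.loc[keep, idx]
        z = block.sub(mean.loc[keep], axis=0).div(sd.loc[keep], axis=0)
        pieces.append(z)
        records.append(
            pd.DataFrame(
                {
                    "dataset": str(batch),
                    "gene": keep,
                    "mean": mean.loc[keep].to_numpy(),
                    "sd": sd.loc[keep].to_numpy(),
                }
            )
        )
    matrix = pd.concat(pieces, axis=1).loc[:, cohort.expr.columns]
    transform = pd.concat(records, ignore_index=True)
    return HarmonizedMatrix(
        matrix=matrix,
        samples=cohort.samples.copy(),
        transform=transform,
        provenance=[cohort.name],
        dropped_genes=dropped,
    )


def merge_cohorts(cohorts: list[HarmonizedMatrix]) -> HarmonizedMatrix:
    """Column-concatenate harmonized cohorts on their shared gene set."""
    if not cohorts:
        raise ConfigError("merge_cohorts requires at least one cohort")
    if len(cohorts) == 1:
        return cohorts[0]
    shared = cohorts[0].matrix.index
    for hm in cohorts[1:]:
        shared = shared.intersection(hm.matrix.index)
    if len(shared) == 0:
        raise DataError("empty gene intersection across cohorts")
    all_samples = pd.concat([hm.samples for hm in cohorts])
    if all_samples.index.duplicated().any():
        dupes = all_samples.index[all_samples.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample ids across cohorts: {dupes[:5]}")
    matrix = pd.concat([hm.matrix.loc[shared] for hm in cohorts], axis=1)
    transform = pd.concat([hm.transform for hm in cohorts], ignore_index=True)
    transform = transform[transform["gene"].isin(shared)].reset_index(drop=True)
    dropped: dict[str, list[str]] = {}
    for hm in cohorts:
        dropped.update(hm.dropped_genes)
    return HarmonizedMatrix(
        matrix=matrix,
        samples=all_samples,
        transform=transform,
        provenance=[p for hm in cohorts for p in hm.provenance],
        dropped_genes=dropped,
    )


def project_samples(
    hm: HarmonizedMatrix, expr: pd.DataFrame, dataset: str
) -> pd.DataFrame:
    """Standardize new samples of a known dataset with its stored (mean, sd).

    Projecting the training samples of ``dataset`` reproduces the harmonized
    matrix exactly (idempotence of the stored-parameter transform).
    """
    rec = hm.transform[hm.transform["dataset"] == str(dataset)]
    if rec.empty:
        raise ConfigError(f"no stored transform for dataset {dataset!r}")
    rec = rec.set_index("gene")
    genes = hm.matrix.index.intersection(expr.index).intersection(rec.index)
    if len(genes) == 0:
        raise DataError("no overlap between new matrix and stored transform genes")
    block = expr.loc[genes]
    return block.sub(rec["mean"].loc[genes], axis=0).div(rec["sd"].loc[genes], axis=0)


def harmonize_cohorts(
    cohorts: list[ExpressionCohort], force_log2_intensity: bool = False
) -> HarmonizedMatrix:
    """Full harmonization: log2(x+1) -> center/scale per dataset -> merge."""
    return merge_cohorts(
        [center_and_scale(log2p1_transform(c, force=force_log2_intensity)) for c in cohorts]
    )
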