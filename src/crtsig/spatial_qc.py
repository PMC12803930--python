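"""Digital-spatial-profiling quality control and normalization.

Implements the segment-level QC thresholds used for GeoMx whole-transcriptome
data, Grubbs-based probe outlier removal, geometric-mean aggregation of probes
into gene-level counts, per-segment limits of quantification (LOQ), detection
filters and third-quartile (Q3) normalization.

Boundary semantics follow the stated rules exactly: thresholds phrased as
"> x" are strict, thresholds phrased as "minimum of x" are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import GEO_CLIP, geomean, geosd
from .errors import ConfigError, DataError

TUMOR = "tumor"
STROMA = "stroma"

#: Metadata columns every segment record must provide.
SEGMENT_COLUMNS = (
    "patient_id",
    "compartment",
    "raw_reads",
    "pct_trimmed",
    "pct_stitched",
    "pct_aligned",
    "pct_saturation",
    "nuclei",
    "area",
    "ntc_count",
)


@dataclass
class SpatialExperiment:
    """Probe x segment counts plus segment metadata and the probe -> target map.

    ``probes`` is indexed by probe id with columns ``target`` (gene id; negative
    controls carry their own pseudo-target) and ``is_negative``. ``segments``
    is indexed by segment id with the :data:`SEGMENT_COLUMNS` metadata.
    """

    counts: pd.DataFrame
    probes: pd.DataFrame
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.probes.index):
            if set(self.counts.index) != set(self.probes.index):
                raise DataError("counts rows and probe table disagree")
            self.probes = self.probes.loc[self.counts.index]
        if not self.counts.columns.equals(self.segments.index):
            if set(self.counts.columns) != set(self.segments.index):
                raise DataError("counts columns and segment table disagree")
            self.segments = self.segments.loc[self.counts.columns]
        if self.probes["target"].isna().any():
            raise DataError("every probe must map to exactly one target")
        neg_targets = set(self.probes.loc[self.probes["is_negative"], "target"])
        bio_targets = set(self.probes.loc[~self.probes["is_negative"], "target"])
        if neg_targets & bio_targets:
            raise DataError("negative-control probes overlap biological targets")

    @property
    def negative_probes(self) -> pd.Index:
        return self.probes.index[self.probes["is_negative"]]

    def neg_geomean(self) -> pd.Series:
        """Per-segment geometric mean of negative-control probe counts."""
        neg = self.counts.loc[self.negative_probes]
        return neg.apply(lambda col: geomean(col), axis=0)


@dataclass
class GeneMatrix:
    """Target x segment gene-level counts with QC state.

    ``counts`` holds biological targets only; negative-control probe counts are
    kept at probe level in ``neg_counts`` because the LOQ is defined on them.
    """

    counts: pd.DataFrame
    neg_counts: pd.DataFrame
    segments: pd.DataFrame
    loq: pd.Series | None = None
    detection: pd.DataFrame | None = None
    norm_factors: pd.Series | None = None


@dataclass(frozen=True)
class SegmentQcThresholds:
    """Study-specific segment QC rules; attribute names double as rule names."""

    min_raw_reads: int = 1000        # inclusive
    min_pct_trimmed: float = 80.0    # strict >
    min_pct_stitched: float = 80.0   # strict >
    min_pct_aligned: float = 75.0    # strict >
    min_pct_saturation: float = 50.0  # strict >
    min_neg_geomean: float = 1.0     # inclusive; per-segment geometric mean
    max_ntc_count: int = 9000        # inclusive
    min_nuclei: int = 20             # inclusive
    min_area: float = 1000.0         # inclusive, square micrometers


def segment_qc(
    experiment: SpatialExperiment,
    thresholds: SegmentQcThresholds = SegmentQcThresholds(),
) -> tuple[list[str], pd.DataFrame]:
    """Classify segments into passes and failures with per-rule reasons.

    Returns the list of passing segment ids and a table of failing segments
    whose ``reasons`` column lists every violated rule.
    """
    seg = experiment.segments
    missing_cols = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
    if missing_cols:
        raise DataError(f"segment metadata lacks columns {missing_cols}")
    for col in SEGMENT_COLUMNS:
        if seg[col].isna().any():
            bad = seg.index[seg[col].isna()][0]
            raise DataError(f"segment {bad!r}: missing metric {col!r}")
    neg_gm = experiment.neg_geomean()
    t = thresholds
    rules = {
        "raw_reads": seg["raw_reads"] >= t.min_raw_reads,
        "pct_trimmed": seg["pct_trimmed"] > t.min_pct_trimmed,
        "pct_stitched": seg["pct_stitched"] > t.min_pct_stitched,
        "pct_aligned": seg["pct_aligned"] > t.min_pct_aligned,
        "pct_saturation": seg["pct_saturation"] > t.min_pct_saturation,
        "neg_geomean": neg_gm >= t.min_neg_geomean,
        "ntc_count": seg["ntc_count"] <= t.max_ntc_count,
        "nuclei": seg["nuclei"] >= t.min_nuclei,
        "area": seg["area"] >= t.min_area,
    }
    ok = pd.DataFrame(rules)
    passed = ok.all(axis=1)
    failed = ok.index[~passed]
    fail = pd.DataFrame(
        {"reasons": [sorted(ok.columns[~ok.loc[s]]) for s in failed]}, index=failed
    )
    return list(seg.index[passed]), fail


def filter_segments(experiment: SpatialExperiment, keep: list[str]) -> SpatialExperiment:
    """Restrict an experiment to the given segment ids."""
    return SpatialExperiment(
        counts=experiment.counts.loc[:, keep],
        probes=experiment.probes.copy(),
        segments=experiment.segments.loc[keep],
    )


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size n."""
    if n < 3:
        raise ConfigError("Grubbs test requires n >= 3")
    t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def _grubbs_flags(values: np.ndarray, alpha: float) -> np.ndarray:
    """Iterated two-sided Grubbs outlier flags on a 1-d array (True = outlier)."""
    flags = np.zeros(values.size, dtype=bool)
    active = np.arange(values.size)
    while active.size >= 3:
        x = values[active]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        if dev[i] / sd > grubbs_critical(active.size, alpha):
            flags[active[i]] = True
            active = np.delete(active, i)
        else:
            break
    return flags


def probe_qc(
    experiment: SpatialExperiment,
    alpha: float = 0.01,
    global_ratio: float = 0.10,
    local_flag_rate: float = 0.20,
) -> tuple[SpatialExperiment, pd.DataFrame]:
    """Local (Grubbs) and global probe outlier removal.

    Local: per target and segment, a two-sided Grubbs test at ``alpha`` on
    log2(count+1) across the target's probes; flagged values become missing
    (NaN). Targets with fewer than 3 probes are skipped with a warning.

    Global: a probe is removed entirely when its geometric mean across
    segments falls below ``global_ratio`` of the geometric mean of all probes
    of its target (negative controls are exempt) or when it is locally flagged
    in more than ``local_flag_rate`` of segments.

    Returns the filtered experiment (counts as float with NaNs for local
    flags) and a per-probe report.
    """
    counts = experiment.counts.astype(float).copy()
    probes = experiment.probes
    log2c = np.log2(counts.to_numpy() + 1.0)
    values = counts.to_numpy()
    n_seg = counts.shape[1]
    local_flags = np.zeros(counts.shape, dtype=bool)
    skipped: list[str] = []
    for target, idx in probes.groupby("target", sort=False).groups.items():
        rows = probes.index.get_indexer(idx)
        if rows.size < 3:
            skipped.append(str(target))
            continue
        for s in range(n_seg):
            col = log2c[rows, s]
            fl = _grubbs_flags(col, alpha)
            if fl.any():
                local_flags[rows[fl], s] = True
    if skipped:
        warnings.warn(
            f"{len(skipped)} target(s) with <3 probes skipped for Grubbs testing",
            stacklevel=2,
        )
    values = values.copy()
    values[local_flags] = np.nan
    counts = pd.DataFrame(values, index=counts.index, columns=counts.columns)

    probe_gm = counts.apply(lambda row: geomean(row), axis=1)
    target_gm = probe_gm.groupby(probes["target"]).transform(lambda g: g.mean())
    local_rate = pd.Series(local_flags.mean(axis=1), index=counts.index)
    low_ratio = (probe_gm < global_ratio * target_gm) & ~probes["is_negative"]
    too_flagged = local_rate > local_flag_rate
    removed = low_ratio | too_flagged
    report = pd.DataFrame(
        {
            "target": probes["target"],
            "is_negative": probes["is_negative"],
            "geomean": probe_gm,
            "target_geomean": target_gm,
            "local_flag_rate": local_rate,
            "removed_low_ratio": low_ratio,
            "removed_local_rate": too_flagged,
            "removed": removed,
        }
    )
    keep = counts.index[~removed]
    filtered = SpatialExperiment(
        counts=counts.loc[keep],
        probes=probes.loc[keep].copy(),
        segments=experiment.segments.copy(),
    )
    return filtered, report


def aggregate_targets(experiment: SpatialExperiment) -> GeneMatrix:
    """Collapse probes to gene-level counts by per-segment geometric mean.

    Single-probe targets pass through unchanged; a target with all probes
    missing in a segment yields a missing value. Negative-control probes stay
    at probe level for the LOQ computation.
    """
    bio = experiment.probes.index[~experiment.probes["is_negative"]]
    neg = experiment.negative_probes
    bio_counts = experiment.counts.loc[bio]
    targets = experiment.probes.loc[bio, "target"]
    logc = np.log(np.maximum(bio_counts.to_numpy(dtype=float), GEO_CLIP))
    logc[np.isnan(bio_counts.to_numpy(dtype=float))] = np.nan
    logdf = pd.DataFrame(logc, index=bio_counts.index, columns=bio_counts.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        agg = np.exp(logdf.groupby(targets, sort=True).mean())
    return GeneMatrix(
        counts=agg,
        neg_counts=experiment.counts.loc[neg].astype(float),
        segments=experiment.segments.copy(),
    )


def compute_loq(genes: GeneMatrix, n_sd: float = 2.0, floor: float = 2.0) -> GeneMatrix:
    """Per-segment limit of quantification from the negative controls.

    LOQ_s = geomean(neg_s) * gSD(neg_s)**n_sd, floored at ``floor``; gSD is
    exp of the (n-1)-denominator SD of natural-log counts. Detection is
    ``count > LOQ`` (strict).
    """
    loq = {}
    for s in genes.neg_counts.columns:
        col = genes.neg_counts[s].dropna()
        if col.size < 2:
            raise DataError(f"segment {s!r}: <2 negative probes, cannot compute LOQ")
        loq[s] = max(geomean(col) * geosd(col) ** n_sd, floor)
    loq = pd.Series(loq, name="loq").loc[genes.counts.columns]
    detection = genes.counts.gt(loq, axis=1) & genes.counts.notna()
    return replace(genes, loq=loq, detection=detection)


def detection_filters(
    genes: GeneMatrix, segment_rate: float = 0.10, gene_rate: float = 0.10
) -> GeneMatrix:
    """Drop poorly detected segments, then poorly detected genes.

    Order matters: segments with a gene detection rate below ``segment_rate``
    are removed first; genes detected in fewer than ``gene_rate`` of the
    surviving segments are removed second.
    """
    if genes.detection is None or genes.loq is None:
        raise DataError("compute_loq must run before detection_filters")
    det = genes.detection
    seg_rate = det.mean(axis=0)
    keep_seg = seg_rate.index[(seg_rate >= segment_rate).to_numpy()]
    if len(keep_seg) == 0:
        raise DataError("no segments pass detection filter")
    det = det.loc[:, keep_seg]
    g_rate = det.mean(axis=1)
    keep_gene = g_rate.index[(g_rate >= gene_rate).to_numpy()]
    return GeneMatrix(
        counts=genes.counts.loc[keep_gene, keep_seg],
        neg_counts=genes.neg_counts.loc[:, keep_seg],
        segments=genes.segments.loc[keep_seg],
        loq=genes.loq.loc[keep_seg],
        detection=det.loc[keep_gene],
    )


def q3_normalize(genes: GeneMatrix) -> GeneMatrix:
    """Third-quartile normalization across segments.

    Q3_s is the 75th percentile (linear interpolation) of the biological
    target counts of segment s; each segment is divided by
    Q3_s / geomean(all Q3), so the geometric mean of normalized Q3 values
    equals the pre-normalization geometric mean of Q3s.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q3 = genes.counts.apply(lambda col: np.nanquantile(col, 0.75), axis=0)
    if (q3 <= 0).any() or q3.isna().any():
        bad = q3.index[(q3 <= 0) | q3.isna()][0]
        raise DataError(f"segment {bad!r}: nonpositive Q3, cannot normalize")
    target = geomean(q3, clip=0.0)
    factors = q3 / target
    return replace(
        genes,
        counts=genes.counts.div(factors, axis=1),
        norm_factors=pd.Series(factors, name="norm_factor"),
    )


def run_spatial_qc(
    experiment: SpatialExperiment,
    thresholds: SegmentQcThresholds = SegmentQcThresholds(),
    alpha: float = 0.01,
    loq_sd: float = 2.0,
    loq_floor: float = 2.0,
    segment_rate: float = 0.10,
    gene_rate: float = 0.10,
) -> tuple[GeneMatrix, dict]:
    """Full QC chain: segment QC -> probe QC -> aggregation -> LOQ ->
    detection filters -> Q3 normalization. Returns the normalized gene matrix
    and a report dictionary."""
    passed, fail = segment_qc(experiment, thresholds)
    if not passed:
        raise DataError("no segments pass segment QC")
    exp = filter_segments(experiment, passed)
    exp, probe_report = probe_qc(exp, alpha=alpha)
    gm = aggregate_targets(exp)
    gm = compute_loq(gm, n_sd=loq_sd, floor=loq_floor)
    gm = detection_filters(gm, segment_rate=segment_rate, gene_rate=gene_rate)
    gm = q3_normalize(gm)
    report = {
        "segments_failed": {k: v for k, v in fail["reasons"].items()},
        "probes_removed": probe_report.index[probe_report["removed"]].tolist(),
        "n_segments_final": int(gm.counts.shape[1]),
        "n_genes_final": int(gm.counts.shape[0]),
    }
    return gm, report
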