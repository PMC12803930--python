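"""Synthetic bulk and spatial cohorts with known ground truth.

The generators emulate the study conditions every downstream stage is
verified against: multiple bulk datasets with platform-specific distributions
(log-normal microarray intensities vs negative-binomial RNA-seq counts),
gene-wise per-dataset batch offsets and scale jitter, Mandard-TRG-derived
response labels with the mid-responder grade to exclude, and planted
response-associated genes with configured log2 fold-changes; for spatial
data, paired tumor/stroma segments per patient, per-gene patient random
intercepts, multi-probe targets with Poisson negative controls, nuclei
counts, and injected QC-failing segments and probes.

Planted effects are symmetric: responders get +lfc/2 and non-responders
-lfc/2 on the log2 scale, so the responder-minus-non-responder difference is
exactly the configured lfc; mid-responders sit in between at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    NON_RESPONDER,
    PLATFORM_COUNT,
    PLATFORM_INTENSITY,
    RESPONDER,
    TRG_RESPONSE_MAP,
    ExpressionCohort,
)
from .errors import ConfigError
from .spatial_qc import STROMA as STROMA_C
from .spatial_qc import TUMOR as TUMOR_C
from .spatial_qc import SpatialExperiment

CATEGORY_TUMOR = "tumor_only"
CATEGORY_STROMA = "stroma_only"
CATEGORY_OPPOSING = "opposing"


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


@dataclass(frozen=True)
class BulkSimConfig:
    """Configuration of the multi-dataset bulk simulation.

    Defaults reflect a realistic multi-cohort rectal-cancer meta-analysis:
    datasets of a few dozen pre-treatment samples each, roughly 45% of
    evaluable patients responding (TRG 1-2), ~15% mid-responders (TRG 3),
    gene-wise batch offsets comparable to biological variation, and residual
    noise of one log2 unit on intensity platforms.
    """

    n_datasets: int = 2
    genes: int = 2000
    samples_per_dataset: int = 60
    platform_per_dataset: tuple[str, ...] | None = None  # default alternates
    responder_fraction: float = 0.45
    mid_fraction: float = 0.15
    trg_distribution: tuple[float, ...] | None = None  # grades 1..5
    planted_genes: tuple[tuple[int, float], ...] = ()
    batch_offset_sd: float = 0.8
    batch_scale_sd: float = 0.1
    noise_sd: float = 1.0
    nb_dispersion: float = 0.15
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    seed: int = 0

    def platforms(self) -> tuple[str, ...]:
        if self.platform_per_dataset is not None:
            return tuple(self.platform_per_dataset)
        return tuple(
            PLATFORM_INTENSITY if d % 2 == 0 else PLATFORM_COUNT
            for d in range(self.n_datasets)
        )

    def trg_probs(self) -> np.ndarray:
        if self.trg_distribution is not None:
            p = np.asarray(self.trg_distribution, dtype=float)
        else:
            rf, mid = self.responder_fraction, self.mid_fraction
            p = np.array(
                [
                    rf * (1 - mid) / 2,
                    rf * (1 - mid) / 2,
                    mid,
                    (1 - rf) * (1 - mid) / 2,
                    (1 - rf) * (1 - mid) / 2,
                ]
            )
        return p

    def validate(self) -> None:
        if self.n_datasets < 1 or self.genes < 1 or self.samples_per_dataset < 1:
            raise ConfigError("dimensions must be positive")
        if not 0 < self.responder_fraction < 1:
            raise ConfigError("responder_fraction must lie in (0, 1)")
        if self.noise_sd <= 0 or self.nb_dispersion <= 0:
            raise ConfigError("noise_sd and nb_dispersion must be positive")
        if self.batch_offset_sd < 0 or self.batch_scale_sd < 0:
            raise ConfigError("batch SDs must be nonnegative")
        p = self.trg_probs()
        if p.size != 5 or (p < 0).any() or abs(p.sum() - 1) > 1e-8:
            raise ConfigError("trg_distribution must be 5 nonnegative probs summing to 1")
        evaluable = p[0] + p[1] + p[3] + p[4]
        if evaluable <= 0:
            raise ConfigError("trg_distribution leaves no evaluable (non-TRG-3) mass")
        if abs((p[0] + p[1]) / evaluable - self.responder_fraction) > 1e-6:
            raise ConfigError(
                "responder_fraction inconsistent with trg_distribution "
                "(grades 1-2 responder, 4-5 non-responder)"
            )
        idx = [g for g, _ in self.planted_genes]
        if len(set(idx)) != len(idx):
            raise ConfigError("planted gene indices must be unique")
        if any(g < 0 or g >= self.genes for g in idx):
            raise ConfigError("planted gene index out of range")
        platforms = self.platforms()
        if len(platforms) != self.n_datasets or any(
            pf not in (PLATFORM_INTENSITY, PLATFORM_COUNT) for pf in platforms
        ):
            raise ConfigError("platform_per_dataset must name intensity/count per dataset")


def generate_bulk_cohorts(
    config: BulkSimConfig,
) -> tuple[list[ExpressionCohort], pd.DataFrame]:
    """Simulate bulk cohorts; returns (cohorts, planted-gene truth table).

    Intensity platforms emit positive reals (2**signal with Gaussian log2
    noise); count platforms emit negative-binomial integers with gene-specific
    log-normally distributed means. Batch structure is an additive gene-wise
    log2 offset plus multiplicative scale jitter per dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.genes)
    lfc = np.zeros(config.genes)
    for g, effect in config.planted_genes:
        lfc[g] = effect
    platforms = config.platforms()
    trg_probs = config.trg_probs()
    cohorts: list[ExpressionCohort] = []
    for d in range(config.n_datasets):
        name = f"d{d}"
        n = config.samples_per_dataset
        offset = rng.normal(0.0, config.batch_offset_sd, config.genes)
        scale = np.exp(rng.normal(0.0, config.batch_scale_sd, config.genes))
        trg = rng.choice(np.arange(1, 6), size=n, p=trg_probs)
        response = np.array([TRG_RESPONSE_MAP[int(t)] for t in trg])
        y = np.where(response == RESPONDER, 0.5, np.where(response == NON_RESPONDER, -0.5, 0.0))
        signal = (
            baseline[:, None]
            + offset[:, None]
            + scale[:, None] * (lfc[:, None] * y[None, :])
        )
        if platforms[d] == PLATFORM_INTENSITY:
            values = 2.0 ** (signal + rng.normal(0.0, config.noise_sd, signal.shape))
        else:
            mu = 2.0**signal
            r = 1.0 / config.nb_dispersion
            values = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
        sample_ids = [f"{name}_s{i:03d}" for i in range(n)]
        expr = pd.DataFrame(values, index=genes, columns=sample_ids)
        samples = pd.DataFrame(
            {
                "batch": name,
                "platform": platforms[d],
                "trg": trg,
                "response": response,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        cohorts.append(ExpressionCohort(name=name, expr=expr, samples=samples))
    truth = pd.DataFrame(
        {
            "gene_id": [genes[g] for g, _ in config.planted_genes],
            "lfc": [effect for _, effect in config.planted_genes],
        }
    )
    return cohorts, truth


#: Segment-QC sabotage values, each violating exactly one threshold.
_SEGMENT_FAILURES = {
    "raw_reads": 500,
    "pct_trimmed": 70.0,
    "pct_stitched": 72.0,
    "pct_aligned": 60.0,
    "pct_saturation": 40.0,
    "ntc_count": 9500,
    "nuclei": 10,
    "area": 500.0,
}


@dataclass(frozen=True)
class SpatialSimConfig:
    """Configuration of the paired tumor/stroma spatial simulation.

    Each patient contributes one tumor and one stroma segment (unless sampled
    into the dropout fraction), with a per-gene patient random intercept, a
    gene-specific tumor-vs-stroma baseline separation, multi-probe targets
    with log-normal probe efficiencies, and Poisson negative-control probes
    sharing a small mean.
    """

    n_patients: int = 50
    targets: int = 100
    probes_per_target: int = 4
    n_negative_probes: int = 20
    planted_tumor_genes: tuple[tuple[int, float], ...] = ()
    planted_stroma_genes: tuple[tuple[int, float], ...] = ()
    planted_opposing_genes: tuple[tuple[int, float], ...] = ()
    responder_fraction: float = 0.5
    patient_intercept_sd: float = 0.5
    compartment_sep_sd: float = 1.0
    noise_sd: float = 0.7
    probe_efficiency_sd: float = 0.15
    probe_noise_sd: float = 0.3
    neg_mean: float = 3.0
    nuclei_range: tuple[int, int] = (50, 2000)
    area_range: tuple[float, float] = (2000.0, 50000.0)
    qc_fail_segment_fraction: float = 0.0
    qc_fail_probe_fraction: float = 0.0
    dropout_fraction: float = 0.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    seed: int = 0

    def planted(self) -> list[tuple[int, float, str]]:
        out = [(g, e, CATEGORY_TUMOR) for g, e in self.planted_tumor_genes]
        out += [(g, e, CATEGORY_STROMA) for g, e in self.planted_stroma_genes]
        out += [(g, e, CATEGORY_OPPOSING) for g, e in self.planted_opposing_genes]
        return out

    def validate(self) -> None:
        if min(self.n_patients, self.targets, self.probes_per_target) < 1:
            raise ConfigError("dimensions must be positive")
        if self.n_negative_probes < 2:
            raise ConfigError("need >=2 negative probes for the LOQ")
        if not 0 < self.responder_fraction < 1:
            raise ConfigError("responder_fraction must lie in (0, 1)")
        for frac in (self.qc_fail_segment_fraction, self.qc_fail_probe_fraction,
                     self.dropout_fraction):
            if not 0 <= frac <= 1:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.patient_intercept_sd < 0 or self.noise_sd <= 0:
            raise ConfigError("invalid variance parameters")
        idx = [g for g, _, _ in self.planted()]
        if len(set(idx)) != len(idx):
            raise ConfigError("planted gene sets must be pairwise disjoint")
        if any(g < 0 or g >= self.targets for g in idx):
            raise ConfigError("planted gene index out of range")


def generate_spatial_cohort(
    config: SpatialSimConfig,
) -> tuple[SpatialExperiment, pd.DataFrame]:
    """Simulate a paired tumor/stroma cohort; returns (experiment, truth).

    The truth table lists every planted marker with its category and log2
    fold-change; injected QC failures are recorded in the metadata columns
    ``qc_injected`` (segments) and ``qc_injected`` (probes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.targets)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.targets)
    comp_sep = rng.normal(0.0, config.compartment_sep_sd, config.targets)
    lfc_tumor = np.zeros(config.targets)
    lfc_stroma = np.zeros(config.targets)
    for g, e, cat in config.planted():
        if cat == CATEGORY_TUMOR:
            lfc_tumor[g] = e
        elif cat == CATEGORY_STROMA:
            lfc_stroma[g] = e
        else:
            lfc_tumor[g], lfc_stroma[g] = e, -e

    n_resp = int(round(config.n_patients * config.responder_fraction))
    responses = np.array(
        [RESPONDER] * n_resp + [NON_RESPONDER] * (config.n_patients - n_resp)
    )
    rng.shuffle(responses)
    patient_ids = [f"p{i:03d}" for i in range(config.n_patients)]
    intercepts = rng.normal(
        0.0, config.patient_intercept_sd, (config.n_patients, config.targets)
    )
    n_drop = int(round(config.dropout_fraction * config.n_patients))
    dropout = set(rng.choice(config.n_patients, size=n_drop, replace=False).tolist())
    drop_side = {i: rng.choice([TUMOR_C, STROMA_C]) for i in sorted(dropout)}

    probe_ids: list[str] = []
    probe_target: list[str] = []
    for g in genes:
        for j in range(config.probes_per_target):
            probe_ids.append(f"{g}_p{j + 1}")
            probe_target.append(g)
    neg_ids = [f"NegProbe{j:02d}" for j in range(config.n_negative_probes)]
    # Persistent probe efficiencies are clipped at 2 sigma: an unbounded draw
    # would occasionally create a probe that is a genuine, consistent outlier
    # indistinguishable from an injected failure. Per-segment lognormal
    # overdispersion (probe_noise_sd) gives within-target contrasts a noise
    # floor beyond Poisson counting noise.
    eff_log = rng.normal(0.0, config.probe_efficiency_sd, len(probe_ids))
    clip = 2.0 * config.probe_efficiency_sd
    efficiency = np.exp(np.clip(eff_log, -clip, clip))

    # Inject globally failing probes: at most one per target so Grubbs testing
    # keeps >=3 clean probes per target, and only on adequately expressed
    # targets — on a near-zero target a crippled probe is indistinguishable
    # from background and no QC rule could (or should) flag it.
    n_bad_probes = int(round(config.qc_fail_probe_fraction * len(probe_ids)))
    eligible = np.flatnonzero(baseline >= 5.0)
    n_bad_probes = min(n_bad_probes, eligible.size)
    bad_targets = rng.choice(eligible, size=n_bad_probes, replace=False)
    probe_injected = np.zeros(len(probe_ids), dtype=bool)
    for t in bad_targets:
        j = int(rng.integers(config.probes_per_target))
        k = t * config.probes_per_target + j
        probe_injected[k] = True
        efficiency[k] = 0.02

    seg_rows = []
    columns = {}
    for i, pid in enumerate(patient_ids):
        y = 0.5 if responses[i] == RESPONDER else -0.5
        compartments = [TUMOR_C, STROMA_C]
        if i in dropout:
            compartments = [c for c in compartments if c != drop_side[i]]
        for comp in compartments:
            sid = f"{pid}_{'T' if comp == TUMOR_C else 'S'}"
            is_tumor = comp == TUMOR_C
            mean_log2 = (
                baseline
                + intercepts[i]
                + (comp_sep if is_tumor else 0.0)
                + (lfc_tumor if is_tumor else lfc_stroma) * y
                + rng.normal(0.0, config.noise_sd, config.targets)
            )
            mu_gene = 2.0**mean_log2
            mu_probe = np.repeat(mu_gene, config.probes_per_target) * efficiency
            mu_probe = mu_probe * np.exp(
                rng.normal(0.0, config.probe_noise_sd, mu_probe.size)
            )
            counts = rng.poisson(mu_probe)
            neg_counts = rng.poisson(config.neg_mean, config.n_negative_probes)
            columns[sid] = np.concatenate([counts, neg_counts])
            seg_rows.append(
                {
                    "segment_id": sid,
                    "patient_id": pid,
                    "compartment": comp,
                    "response": responses[i],
                    "raw_reads": int(rng.integers(50_000, 200_000)),
                    "pct_trimmed": float(rng.uniform(90, 99.5)),
                    "pct_stitched": float(rng.uniform(90, 99.5)),
                    "pct_aligned": float(rng.uniform(85, 98)),
                    "pct_saturation": float(rng.uniform(65, 95)),
                    "nuclei": int(rng.integers(config.nuclei_range[0], config.nuclei_range[1] + 1)),
                    "area": float(rng.uniform(*config.area_range)),
                    "ntc_count": int(rng.integers(0, 500)),
                    "qc_injected": "",
                }
            )

    segments = pd.DataFrame(seg_rows).set_index("segment_id")
    n_bad_seg = int(round(config.qc_fail_segment_fraction * len(segments)))
    bad_seg = rng.choice(len(segments), size=n_bad_seg, replace=False)
    rules = list(_SEGMENT_FAILURES)
    for k in bad_seg:
        rule = rules[int(rng.integers(len(rules)))]
        segments.iloc[k, segments.columns.get_loc(rule)] = _SEGMENT_FAILURES[rule]
        segments.iloc[k, segments.columns.get_loc("qc_injected")] = rule

    counts = pd.DataFrame(columns, index=probe_ids + neg_ids)
    probes = pd.DataFrame(
        {
            "target": probe_target + ["NegProbe"] * config.n_negative_probes,
            "is_negative": [False] * len(probe_ids) + [True] * config.n_negative_probes,
            "qc_injected": probe_injected.tolist() + [False] * config.n_negative_probes,
        },
        index=pd.Index(probe_ids + neg_ids, name="probe_id"),
    )
    experiment = SpatialExperiment(counts=counts, probes=probes, segments=segments)
    planted = config.planted()
    truth = pd.DataFrame(
        {
            "gene_id": [genes[g] for g, _, _ in planted],
            "category": [cat for _, _, cat in planted],
            "lfc": [e for _, e, _ in planted],
        }
    )
    return experiment, truth
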