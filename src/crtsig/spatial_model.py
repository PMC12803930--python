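"""Per-gene mixed models, bootstrap consensus and pseudo-bulk construction.

Each gene's log2 Q3-normalized expression is modeled as

    y = mu + tumor + response-in-tumor + response-in-stroma + u_patient + eps

with a patient random intercept absorbing patient and batch technical
variability. The parametrization uses within-compartment response contrasts
directly: ``beta_response_tumor`` and ``beta_response_stroma`` are the
responder-minus-non-responder effects inside each compartment, and the
interaction contrast is their difference. p-values use Satterthwaite degrees
of freedom and are BH-adjusted per contrast family across genes.

Robustness to patient sampling is assessed by refitting on patient
resamples: only genes significant in every resample enter the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lmm import PatientBlockLMM
from ._stats import bh_adjust
from .cohort import NON_RESPONDER, RESPONDER
from .errors import DataError
from .spatial_qc import STROMA, TUMOR, GeneMatrix

CATEGORIES = ("both", "tumor_only", "stroma_only", "opposing", "none")


@dataclass
class GeneMixedFit:
    """One gene's mixed-model contrasts (q-values filled per-family later)."""

    gene: str
    beta_response_tumor: float
    se_tumor: float
    p_tumor: float
    beta_response_stroma: float
    se_stroma: float
    p_stroma: float
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    df_tumor: float
    df_stroma: float
    df_interaction: float
    sigma_patient2: float
    sigma_resid2: float
    singular: bool
    converged: bool


def log2_expression(genes: GeneMatrix, offset: float = 1.0) -> pd.DataFrame:
    """log2(count + offset) of a (normalized) gene matrix."""
    return np.log2(genes.counts + offset)


def _meta_design(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    for col in ("patient_id", "compartment", "response"):
        if col not in meta.columns:
            raise DataError(f"segment metadata lacks column {col!r}")
    comp = meta["compartment"]
    if not set(comp.unique()) <= {TUMOR, STROMA}:
        raise DataError("compartment must be tumor/stroma")
    if comp.nunique() < 2:
        raise DataError("interaction inestimable: only one compartment present")
    resp = meta["response"]
    if not set(resp.unique()) <= {RESPONDER, NON_RESPONDER}:
        raise DataError("response must be responder/non-responder")
    if resp.nunique() < 2:
        raise DataError("both response classes required")
    t = (comp == TUMOR).to_numpy(dtype=float)
    r = (resp == RESPONDER).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(meta)), t, r * t, r * (1 - t)])
    return X, meta["patient_id"].to_numpy()


_C_TUMOR = np.array([0.0, 0.0, 1.0, 0.0])
_C_STROMA = np.array([0.0, 0.0, 0.0, 1.0])
_C_INTER = np.array([0.0, 0.0, 1.0, -1.0])


def _fit_one(lmm: PatientBlockLMM, y: np.ndarray, gene: str) -> GeneMixedFit:
    fit = lmm.fit(y)
    bt, st, dft, pt = lmm.contrast(fit, _C_TUMOR, y)
    bs, ss, dfs, ps = lmm.contrast(fit, _C_STROMA, y)
    bi, si, dfi, pi = lmm.contrast(fit, _C_INTER, y)
    return GeneMixedFit(
        gene=gene,
        beta_response_tumor=bt, se_tumor=st, p_tumor=pt,
        beta_response_stroma=bs, se_stroma=ss, p_stroma=ps,
        beta_interaction=bi, se_interaction=si, p_interaction=pi,
        df_tumor=dft, df_stroma=dfs, df_interaction=dfi,
        sigma_patient2=fit.sigma_u2, sigma_resid2=fit.sigma_e2,
        singular=fit.singular, converged=fit.converged,
    )


def _fit_ols(X: np.ndarray, y: np.ndarray, gene: str) -> GeneMixedFit:
    """Fixed-effects-only fit (no patient pooling), for calibration studies."""
    from scipy import stats as sps

    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - p)
    cov = s2 * XtX_inv
    out = {}
    for name, c in (("tumor", _C_TUMOR), ("stroma", _C_STROMA), ("interaction", _C_INTER)):
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        out[name] = (est, se, float(n - p), 2.0 * sps.t.sf(abs(est) / se, n - p))
    return GeneMixedFit(
        gene=gene,
        beta_response_tumor=out["tumor"][0], se_tumor=out["tumor"][1],
        p_tumor=out["tumor"][3],
        beta_response_stroma=out["stroma"][0], se_stroma=out["stroma"][1],
        p_stroma=out["stroma"][3],
        beta_interaction=out["interaction"][0], se_interaction=out["interaction"][1],
        p_interaction=out["interaction"][3],
        df_tumor=out["tumor"][2], df_stroma=out["stroma"][2],
        df_interaction=out["interaction"][2],
        sigma_patient2=0.0, sigma_resid2=s2, singular=True, converged=True,
    )


def fit_gene_mixed_model(y: pd.Series, meta: pd.DataFrame) -> GeneMixedFit:
    """Fit the mixed model for a single gene (segments indexed alike)."""
    meta = meta.loc[y.index]
    mask = ~y.isna().to_numpy()
    X, groups = _meta_design(meta.loc[y.index[mask]])
    lmm = PatientBlockLMM(X, groups)
    return _fit_one(lmm, y.to_numpy(dtype=float)[mask], str(y.name))


def fit_all_genes(
    expr: pd.DataFrame, meta: pd.DataFrame, random_effect: bool = True
) -> pd.DataFrame:
    """Fit every gene and BH-adjust p-values within each contrast family.

    ``expr`` is genes x segments (log2 scale); ``meta`` is indexed by segment
    with patient_id, compartment, response. Genes sharing a missingness
    pattern share one precomputed solver. ``random_effect=False`` drops the
    patient intercept (ordinary least squares), kept for calibration studies.
    """
    if not expr.columns.equals(meta.index):
        if set(expr.columns) != set(meta.index):
            raise DataError("expression columns and metadata rows disagree")
        meta = meta.loc[expr.columns]
    rows = []
    values = expr.to_numpy(dtype=float)
    nan_pattern = pd.DataFrame(np.isnan(values), index=expr.index)
    solvers: dict[tuple, PatientBlockLMM] = {}
    for gi, gene in enumerate(expr.index):
        mask = ~nan_pattern.iloc[gi].to_numpy()
        if not random_effect:
            X, _ = _meta_design(meta.loc[expr.columns[mask]])
            rows.append(_fit_ols(X, values[gi][mask], str(gene)))
            continue
        key = tuple(mask)
        if key not in solvers:
            X, groups = _meta_design(meta.loc[expr.columns[mask]])
            solvers[key] = PatientBlockLMM(X, groups)
        rows.append(_fit_one(solvers[key], values[gi][mask], str(gene)))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("gene")
    for fam in ("tumor", "stroma", "interaction"):
        out[f"q_{fam}"] = bh_adjust(out[f"p_{fam}"].to_numpy())
    return out


def classify_compartment_genes(fits: pd.DataFrame, q_threshold: float = 0.05) -> pd.Series:
    """Assign each gene a compartment category from its fitted contrasts.

    Both compartments significant: same effect sign -> ``both``, opposite
    sign -> ``opposing``. One compartment significant -> ``tumor_only`` /
    ``stroma_only``. Otherwise a significant interaction with opposite signs
    -> ``opposing``; else ``none``.
    """
    needed = ["q_tumor", "q_stroma", "q_interaction",
              "beta_response_tumor", "beta_response_stroma"]
    missing = [c for c in needed if c not in fits.columns]
    if missing:
        raise DataError(f"fits table lacks columns {missing}")
    out = {}
    for gene, row in fits.iterrows():
        sig_t = row["q_tumor"] < q_threshold
        sig_s = row["q_stroma"] < q_threshold
        same_sign = row["beta_response_tumor"] * row["beta_response_stroma"] > 0
        if sig_t and sig_s:
            out[gene] = "both" if same_sign else "opposing"
        elif sig_t:
            out[gene] = "tumor_only"
        elif sig_s:
            out[gene] = "stroma_only"
        elif row["q_interaction"] < q_threshold and not same_sign:
            out[gene] = "opposing"
        else:
            out[gene] = "none"
    return pd.Series(out, name="category")


def _significant_genes(fits: pd.DataFrame, q_threshold: float) -> set[str]:
    q = fits[["q_tumor", "q_stroma", "q_interaction"]].min(axis=1)
    return set(fits.index[q < q_threshold])


def intersect_runs(lists: list[set[str]]) -> tuple[pd.Series, set[str]]:
    """Per-gene run counts and the all-runs intersection."""
    counts: dict[str, int] = {}
    for genes in lists:
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    consensus = set.intersection(*lists) if lists else set()
    return pd.Series(counts, dtype=int), consensus


def bootstrap_consensus(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    n_runs: int = 5,
    q_threshold: float = 0.05,
    seed: int = 0,
    replace: bool = True,
    subsample_fraction: float = 0.8,
) -> pd.DataFrame:
    """Patient-resampling consensus of significant genes.

    Each run redraws patients (with replacement by default, keeping the
    cohort size; without replacement a ``subsample_fraction`` subsample),
    refits every gene, and records the genes whose smallest family q-value
    beats the threshold. Only genes significant in every run are in the
    consensus. A resample with a single response class is redrawn (at most
    100 attempts).
    """
    if not expr.columns.equals(meta.index):
        meta = meta.loc[expr.columns]
    patients = pd.unique(meta["patient_id"])
    pat_resp = meta.groupby("patient_id", sort=False)["response"].first()
    for cls in (RESPONDER, NON_RESPONDER):
        if (pat_resp == cls).sum() < 2:
            raise DataError(f"need >=2 patients of class {cls!r}")
    rng = np.random.default_rng(seed)
    lists: list[set[str]] = []
    for _ in range(n_runs):
        for attempt in range(100):
            if replace:
                draw = rng.choice(patients, size=len(patients), replace=True)
            else:
                k = max(2, int(round(subsample_fraction * len(patients))))
                draw = rng.choice(patients, size=k, replace=False)
            if pat_resp.loc[draw].nunique() == 2:
                break
        else:
            raise DataError("could not draw a two-class patient resample in 100 attempts")
        cols, new_meta = [], []
        for j, pid in enumerate(draw):
            seg_ids = meta.index[meta["patient_id"] == pid]
            block = meta.loc[seg_ids].copy()
            block["patient_id"] = f"{pid}*{j}"
            block.index = [f"{s}*{j}" for s in seg_ids]
            new_meta.append(block)
            sub = expr.loc[:, seg_ids].copy()
            sub.columns = block.index
            cols.append(sub)
        fits = fit_all_genes(pd.concat(cols, axis=1), pd.concat(new_meta))
        lists.append(_significant_genes(fits, q_threshold))
    counts, consensus = intersect_runs(lists)
    table = pd.DataFrame(index=expr.index)
    table["n_runs_significant"] = counts.reindex(expr.index).fillna(0).astype(int)
    table["in_consensus"] = table["n_runs_significant"] == n_runs
    return table


def consensus_marker_analysis(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    n_runs: int = 5,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Full-data fits + categories + bootstrap consensus in one table."""
    fits = fit_all_genes(expr, meta)
    fits["category"] = classify_compartment_genes(fits, q_threshold)
    cons = bootstrap_consensus(
        expr, meta, n_runs=n_runs, q_threshold=q_threshold, seed=seed
    )
    return fits.join(cons)


def make_pseudobulk(
    counts: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Nuclei-weighted pseudo-bulk per patient, then log2(v+1).

    ``counts`` is genes x segments on the linear scale. Patients with a
    single available compartment carry that compartment's values unchanged
    before the log2 step. Returns (genes x patients log2 matrix, per-patient
    total nuclei weights).
    """
    if not counts.columns.equals(meta.index):
        meta = meta.loc[counts.columns]
    for col in ("patient_id", "nuclei"):
        if col not in meta.columns:
            raise DataError(f"segment metadata lacks column {col!r}")
    out = {}
    weights = {}
    for pid, seg_ids in meta.groupby("patient_id", sort=True).groups.items():
        nuc = meta.loc[seg_ids, "nuclei"].to_numpy(dtype=float)
        total = nuc.sum()
        if total <= 0:
            raise DataError(f"patient {pid!r}: zero total nuclei")
        block = counts.loc[:, seg_ids].to_numpy(dtype=float)
        out[pid] = block @ (nuc / total)
        weights[pid] = total
    pb = pd.DataFrame(out, index=counts.index)
    return np.log2(pb + 1.0), pd.Series(weights, name="nuclei")
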