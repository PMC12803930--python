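"""Cross-validated differential-expression feature selection.

Per-gene linear models of harmonized expression on batch indicators plus a
responder indicator, moderated with empirical-Bayes variance shrinkage, are
fitted on every combination of ``keep`` out of ``n_folds`` stratified folds
(45 runs for 8 of 10). Per-gene p-values are aggregated across runs by
maximum and mean; the signature is the intersection of two thresholded
analyses (all datasets vs a dataset subset).

The moderated t follows the standard empirical-Bayes closed forms: with
per-gene residual variance s_g^2 on d_g degrees of freedom and a scaled
inverse-chi-square prior (d0, s0^2), the posterior variance is
s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g) and t = beta / (s~_g sqrt(v))
is referred to a t distribution with d0 + d_g degrees of freedom. The prior
is estimated by the method of moments on log s_g^2 across genes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from ._stats import bh_adjust
from .cohort import NON_RESPONDER, RESPONDER, HarmonizedMatrix
from .errors import ConfigError, DataError


@dataclass
class FoldAssignment:
    """Stratified partition of samples into folds."""

    n_folds: int
    fold_of_sample: pd.Series  # fold index per sample id
    strata: pd.Series
    seed: int

    def samples_in(self, folds) -> pd.Index:
        folds = set(folds)
        mask = self.fold_of_sample.isin(folds)
        return self.fold_of_sample.index[mask]


@dataclass
class RunResult:
    """Per-gene statistics of one fold-combination run."""

    run_id: int
    table: pd.DataFrame  # index gene: log_fc, t, p_value, df_total
    d0: float
    s0_sq: float


@dataclass
class CvDeaResult:
    """Per-gene statistics aggregated over all runs."""

    table: pd.DataFrame  # index gene: max_p, mean_p, mean_log_fc, n_runs, q_mean_p
    n_runs: int
    eb_hyperparams: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class SignatureGeneSet:
    """Ordered signature genes plus the record of how they were selected."""

    gene_ids: list[str]
    source: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)


def make_stratified_folds(labels: pd.Series, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Partition samples into ``n_folds`` folds, stratified by response.

    Within each class, samples are shuffled and dealt round-robin so class
    fold sizes differ by at most one. Deterministic for a given seed.
    """
    if n_folds < 2:
        raise ConfigError("n_folds must be >= 2")
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DataError(f"expected exactly two response classes, got {classes}")
    for cls in classes:
        if (labels == cls).sum() == 0:
            raise DataError(f"response class {cls!r} has no samples")
    rng = np.random.default_rng(seed)
    fold = pd.Series(index=labels.index, dtype=int, name="fold")
    for cls in classes:
        idx = labels.index[labels == cls].to_numpy()
        idx = idx[rng.permutation(len(idx))]
        fold.loc[idx] = np.arange(len(idx)) % n_folds
    counts = fold.value_counts()
    if len(counts) < n_folds or (counts == 0).any():
        raise DataError("every fold must be nonempty; reduce n_folds")
    return FoldAssignment(n_folds=n_folds, fold_of_sample=fold, strata=labels.copy(), seed=seed)


def enumerate_fold_combinations(n_folds: int, k: int) -> list[tuple[int, ...]]:
    """All C(n_folds, k) fold subsets in deterministic lexicographic order."""
    if not 0 < k <= n_folds:
        raise ConfigError(f"k must satisfy 0 < k <= n_folds, got k={k}, n_folds={n_folds}")
    return list(itertools.combinations(range(n_folds), k))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        raise ConfigError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_eb_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log s_g^2 against the theoretical
    moments of a scaled F distribution; returns (d0, s0_sq), with d0 = inf
    when the observed spread of log-variances is no larger than expected from
    chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # observed spread no larger than chi-square sampling noise: complete
        # shrinkage to the pooled (arithmetic-mean) variance
        d0 = np.inf
        s0_sq = float(np.mean(s2))
    return float(d0), float(s0_sq)


def _design(batch: pd.Series | None, response: pd.Series) -> tuple[np.ndarray, list[str]]:
    bad = ~response.isin([RESPONDER, NON_RESPONDER])
    if bad.any():
        raise DataError(
            f"response labels must be responder/non-responder; offending sample "
            f"{response.index[bad][0]!r}"
        )
    y01 = (response == RESPONDER).to_numpy(dtype=float)
    cols = [np.ones(len(response))]
    names = ["intercept"]
    if batch is not None:
        levels = sorted(pd.unique(batch))
        for lev in levels[1:]:
            cols.append((batch == lev).to_numpy(dtype=float))
            names.append(f"batch[{lev}]")
    cols.append(y01)
    names.append("response")
    X = np.column_stack(cols)
    # drop aliased batch columns (e.g. empty after subsetting)
    while np.linalg.matrix_rank(X) < X.shape[1]:
        dropped = None
        for j in range(1, X.shape[1] - 1):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                dropped = j
                break
        if dropped is None:
            raise DataError("design matrix rank-deficient: response aliased with batch")
        warnings.warn(f"dropping aliased design column {names[dropped]!r}", stacklevel=2)
        X = np.delete(X, dropped, axis=1)
        del names[dropped]
    return X, names


def fit_moderated_de(
    expr: pd.DataFrame,
    batch: pd.Series | None,
    response: pd.Series,
    moderated: bool = True,
    eb_prior: tuple[float, float] | None = None,
    run_id: int = 0,
) -> RunResult:
    """Per-gene linear model ``expression ~ batch + response``.

    ``expr`` is genes x samples; ``batch``/``response`` are indexed by the
    same samples. With ``moderated=True`` the residual variances are shrunk
    with the empirical-Bayes prior (optionally supplied via ``eb_prior``,
    which the tests use to probe the d0 -> 0 and d0 -> inf limits); with
    ``moderated=False`` ordinary t-statistics are returned.
    """
    for s in (batch, response):
        if s is not None and not s.index.equals(expr.columns):
            raise DataError("annotation index must match expression columns")
    for cls in (RESPONDER, NON_RESPONDER):
        if (response == cls).sum() < 2:
            raise DataError(f"need >=2 samples of class {cls!r}")
    X, names = _design(batch, response)
    n, p = X.shape
    if n <= p:
        raise DataError(f"{n} samples cannot identify {p} coefficients")
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df_resid = n - p
    s2 = (resid**2).sum(axis=0) / df_resid
    b_resp = beta[-1]
    v_resp = XtX_inv[-1, -1]
    if moderated:
        d0, s0_sq = eb_prior if eb_prior is not None else estimate_eb_prior(s2, df_resid)
    else:
        d0, s0_sq = 0.0, float("nan")
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = float(d0 + df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = b_resp / np.sqrt(s2_post * v_resp)
    if np.isinf(df_total):
        pval = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pval = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    table = pd.DataFrame(
        {
            "log_fc": b_resp,
            "t": tstat,
            "p_value": pval,
            "df_total": df_total,
        },
        index=expr.index,
    )
    return RunResult(run_id=run_id, table=table, d0=float(d0), s0_sq=float(s0_sq))


def aggregate_cv_pvalues(runs: list[RunResult]) -> CvDeaResult:
    """Per-gene max/mean p and mean coefficient over all runs."""
    if not runs:
        raise DataError("no runs to aggregate")
    genes = runs[0].table.index
    for r in runs[1:]:
        if not r.table.index.equals(genes):
            raise DataError("runs cover inconsistent gene sets")
    p = np.column_stack([r.table["p_value"].to_numpy() for r in runs])
    fc = np.column_stack([r.table["log_fc"].to_numpy() for r in runs])
    table = pd.DataFrame(
        {
            "max_p": p.max(axis=1),
            "mean_p": p.mean(axis=1),
            "mean_log_fc": fc.mean(axis=1),
            "n_runs": len(runs),
        },
        index=genes,
    )
    # BH-adjusted mean p reported for transparency; never used for selection.
    table["q_mean_p"] = bh_adjust(table["mean_p"].to_numpy())
    return CvDeaResult(
        table=table,
        n_runs=len(runs),
        eb_hyperparams=[(r.d0, r.s0_sq) for r in runs],
    )


def run_cv_dea(
    hm: HarmonizedMatrix,
    datasets: list[str] | None = None,
    n_folds: int = 10,
    keep: int = 8,
    seed: int = 0,
    moderated: bool = True,
    include_batch: bool = True,
) -> CvDeaResult:
    """Full cross-validated analysis on a harmonized matrix.

    Mid-responders and unlabeled samples are excluded before fold
    construction; ``datasets`` restricts the analysis to a subset of batch
    labels (the 4-dataset grouping of the two-analysis design).
    """
    samples = hm.samples
    mask = samples["response"].isin([RESPONDER, NON_RESPONDER])
    if datasets is not None:
        mask &= samples["batch"].astype(str).isin([str(d) for d in datasets])
    sub = samples.index[mask]
    if len(sub) == 0:
        raise DataError("no samples left after response/dataset filtering")
    labels = samples.loc[sub, "response"]
    folds = make_stratified_folds(labels, n_folds=n_folds, seed=seed)
    runs = []
    single_batch = samples.loc[sub, "batch"].nunique() < 2
    for run_id, combo in enumerate(enumerate_fold_combinations(n_folds, keep)):
        take = folds.samples_in(combo)
        batch = None if (not include_batch or single_batch) else samples.loc[take, "batch"]
        runs.append(
            fit_moderated_de(
                hm.matrix.loc[:, take],
                batch,
                samples.loc[take, "response"],
                moderated=moderated,
                run_id=run_id,
            )
        )
    return aggregate_cv_pvalues(runs)


def select_signature_genes(
    result_all: CvDeaResult,
    result_subset: CvDeaResult,
    mean_p_threshold: float = 0.05,
    mode: str = "mean",
) -> SignatureGeneSet:
    """Intersect the thresholded gene lists of the two analyses.

    ``mode='mean'`` thresholds the run-averaged p-value (the signature rule);
    ``mode='max'`` thresholds the maximum p over runs, equivalent to
    intersecting the per-run significant lists (the strict variant). Genes
    are ordered by ascending mean_p of ``result_all``, ties broken by id.
    """
    if mode not in ("mean", "max"):
        raise ConfigError(f"unknown selection mode {mode!r}")
    col = "mean_p" if mode == "mean" else "max_p"
    list_all = result_all.table.index[result_all.table[col] < mean_p_threshold]
    list_sub = result_subset.table.index[result_subset.table[col] < mean_p_threshold]
    inter = set(list_all) & set(list_sub)
    if not inter:
        warnings.warn("signature is empty: thresholded lists do not intersect", stacklevel=2)
    order = result_all.table.loc[sorted(inter)].sort_values(
        ["mean_p"], kind="stable"
    )
    ordered = sorted(order.index, key=lambda g: (order.at[g, "mean_p"], g))
    return SignatureGeneSet(
        gene_ids=list(ordered),
        source={
            "mode": mode,
            "threshold": mean_p_threshold,
            "n_all": int(len(list_all)),
            "n_subset": int(len(list_sub)),
        },
    )
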