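"""Signature evaluation with L2 logistic regression and random forests.

The selected gene set is evaluated by stratified 5-fold cross-validation with
hyperparameter tuning confined to each training split: the ridge penalty of
the logistic model is tuned by inner 5-fold cross-validated AUC over a
20-point log-spaced grid, and the random forest's features-per-split is tuned
by out-of-bag AUC over a 20-point grid with 500 trees fixed. The reported
performance is the mean and standard deviation of the out-of-fold AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .cohort import NON_RESPONDER, RESPONDER, HarmonizedMatrix
from .cv_dea import SignatureGeneSet, make_stratified_folds
from .errors import ConfigError, DataError

L2_LOGISTIC = "l2_logistic"
RANDOM_FOREST = "random_forest"

#: Ridge penalty grid (lambda); sklearn's C is 1/lambda.
LAMBDA_GRID = np.logspace(-4, 2, 20)
N_TREES = 500


@dataclass
class SignatureEvaluation:
    """Cross-validated performance of one classifier on one gene set."""

    method: str
    per_fold_auc: list[float]
    mean_auc: float
    sd_auc: float
    tuned_params: list[dict]
    n_folds: int
    tune_iters: int
    seed: int
    grid: list[float] = field(default_factory=list)


@dataclass
class FittedSignatureModel:
    """A classifier trained on the full harmonized matrix."""

    method: str
    estimator: object
    genes: list[str]
    params: dict
    seed: int


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve in its Mann-Whitney form.

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over all positive/negative
    pairs; computed from midranks so ties are handled exactly.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind not in "bif":
        y = y == RESPONDER
    y = y.astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC requires both classes present")
    r = rankdata(scores)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _as_matrix(matrix) -> pd.DataFrame:
    return matrix.matrix if isinstance(matrix, HarmonizedMatrix) else matrix


def _feature_table(matrix, genes) -> pd.DataFrame:
    m = _as_matrix(matrix)
    gene_ids = list(genes.gene_ids) if isinstance(genes, SignatureGeneSet) else list(genes)
    if not gene_ids:
        raise DataError("empty signature gene set")
    missing = [g for g in gene_ids if g not in m.index]
    if missing:
        if len(missing) / len(gene_ids) > 0.20:
            raise DataError(
                f"{len(missing)}/{len(gene_ids)} signature genes missing from matrix"
            )
        warnings.warn(
            f"imputing harmonized mean (0) for {len(missing)} missing signature gene(s)",
            stacklevel=2,
        )
    X = pd.DataFrame(0.0, index=gene_ids, columns=m.columns)
    present = [g for g in gene_ids if g not in missing]
    X.loc[present] = m.loc[present]
    return X.T  # samples x genes


def _labels01(labels: pd.Series) -> np.ndarray:
    bad = ~labels.isin([RESPONDER, NON_RESPONDER])
    if bad.any():
        raise DataError("labels must be responder/non-responder (exclude mid-responders)")
    return (labels == RESPONDER).to_numpy(dtype=int)


def _rf_grid(n_features: int, tune_iters: int) -> list[int]:
    return sorted(set(np.linspace(1, n_features, tune_iters).round().astype(int)))


def _tune_l2(X: np.ndarray, y: np.ndarray, seed: int, tune_iters: int) -> dict:
    grid = np.logspace(-4, 2, tune_iters)
    labels = pd.Series(np.where(y == 1, RESPONDER, NON_RESPONDER))
    inner = make_stratified_folds(labels, n_folds=5, seed=seed)
    fold = inner.fold_of_sample.to_numpy()
    best = None
    for lam in grid:
        aucs = []
        for f in range(5):
            tr, te = fold != f, fold == f
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            clf = LogisticRegression(C=1.0 / lam, solver="lbfgs", max_iter=2000)
            clf.fit(X[tr], y[tr])
            aucs.append(compute_auc(clf.predict_proba(X[te])[:, 1], y[te]))
        score = float(np.mean(aucs)) if aucs else 0.0
        if best is None or score > best[0]:
            best = (score, lam)
    return {"lambda": float(best[1]), "inner_auc": float(best[0])}


def _tune_rf(X: np.ndarray, y: np.ndarray, seed: int, tune_iters: int) -> dict:
    best = None
    for m in _rf_grid(X.shape[1], tune_iters):
        clf = RandomForestClassifier(
            n_estimators=N_TREES, max_features=m, oob_score=True, random_state=seed
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # some samples may never be OOB
            clf.fit(X, y)
        oob = clf.oob_decision_function_[:, 1]
        ok = ~np.isnan(oob)
        score = compute_auc(oob[ok], y[ok])
        if best is None or score > best[0]:
            best = (score, m)
    return {"max_features": int(best[1]), "oob_auc": float(best[0])}


def _fit_estimator(method: str, X: np.ndarray, y: np.ndarray, params: dict, seed: int):
    if method == L2_LOGISTIC:
        clf = LogisticRegression(
            C=1.0 / params["lambda"], solver="lbfgs", max_iter=2000
        )
    elif method == RANDOM_FOREST:
        clf = RandomForestClassifier(
            n_estimators=N_TREES, max_features=params["max_features"], random_state=seed
        )
    else:
        raise ConfigError(f"unknown method {method!r}")
    clf.fit(X, y)
    return clf


def cross_validate_signature(
    matrix,
    genes,
    labels: pd.Series,
    method: str = L2_LOGISTIC,
    n_folds: int = 5,
    tune_iters: int = 20,
    seed: int = 0,
) -> SignatureEvaluation:
    """Outer stratified CV with inner tuning on training folds only."""
    if method not in (L2_LOGISTIC, RANDOM_FOREST):
        raise ConfigError(f"unknown method {method!r}")
    Xdf = _feature_table(matrix, genes)
    labels = labels.loc[Xdf.index]
    y = _labels01(labels)
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < n_folds:
            raise DataError(
                f"class {cls} has {cnt} samples; need >= n_folds={n_folds}"
            )
    X = Xdf.to_numpy()
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_folds + 1) % (2**31)
    outer = make_stratified_folds(labels, n_folds=n_folds, seed=int(seeds[0]))
    fold = outer.fold_of_sample.to_numpy()
    per_fold, tuned = [], []
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        if len(np.unique(y[te])) < 2:
            raise DataError(f"outer fold {f} is single-class; adjust fold sizes")
        tune = _tune_l2 if method == L2_LOGISTIC else _tune_rf
        params = tune(X[tr], y[tr], int(seeds[1 + f]), tune_iters)
        clf = _fit_estimator(method, X[tr], y[tr], params, int(seeds[1 + n_folds + f]))
        per_fold.append(compute_auc(clf.predict_proba(X[te])[:, 1], y[te]))
        tuned.append(params)
    per_fold = [float(a) for a in per_fold]
    grid = (
        list(np.logspace(-4, 2, tune_iters))
        if method == L2_LOGISTIC
        else [float(m) for m in _rf_grid(X.shape[1], tune_iters)]
    )
    return SignatureEvaluation(
        method=method,
        per_fold_auc=per_fold,
        mean_auc=float(np.mean(per_fold)),
        sd_auc=float(np.std(per_fold, ddof=1)),
        tuned_params=tuned,
        n_folds=n_folds,
        tune_iters=tune_iters,
        seed=seed,
        grid=grid,
    )


def fit_signature_model(
    matrix,
    genes,
    labels: pd.Series,
    method: str = L2_LOGISTIC,
    seed: int = 0,
    params: dict | None = None,
    tune_iters: int = 20,
) -> FittedSignatureModel:
    """Train a final model on all samples (tuning on the full data unless
    explicit hyperparameters are given)."""
    Xdf = _feature_table(matrix, genes)
    labels = labels.loc[Xdf.index]
    y = _labels01(labels)
    X = Xdf.to_numpy()
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    if params is None:
        tune = _tune_l2 if method == L2_LOGISTIC else _tune_rf
        params = tune(X, y, int(seeds[0]), tune_iters)
    clf = _fit_estimator(method, X, y, params, int(seeds[1]))
    return FittedSignatureModel(
        method=method,
        estimator=clf,
        genes=list(Xdf.columns),
        params=params,
        seed=seed,
    )


def score_samples(model: FittedSignatureModel, new_matrix) -> pd.Series:
    """Responder probability (logistic) or vote fraction (forest) per sample.

    ``new_matrix`` must already be on the harmonized scale (project external
    cohorts with their stored or own standardization first). Up to 20% of
    signature genes may be missing and are imputed at the harmonized mean 0.
    """
    Xdf = _feature_table(new_matrix, model.genes)
    scores = model.estimator.predict_proba(Xdf.to_numpy())[:, 1]
    return pd.Series(scores, index=Xdf.index, name="responder_score")
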