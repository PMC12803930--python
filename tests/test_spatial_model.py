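"""Mixed-model contrasts (frozen REML oracle + statsmodels cross-check),
BH adjustment, compartment classification, bootstrap consensus and
pseudo-bulk arithmetic."""

import numpy as np
import pandas as pd
import pytest

import crtsig as cs
from crtsig.errors import DataError
from crtsig.spatial_model import _meta_design, intersect_runs
from conftest import make_segment_meta

# --- frozen fixture: 8 patients, paired segments, fitted once with
# lme4/lmerTest (REML, Satterthwaite) to generate the expected values ---
LMM_VALUES = [
    6.7628, 5.5581, 6.6888, 4.9132, 7.0186, 5.0683, 7.0279, 4.8771,
    6.8032, 5.2734, 5.8688, 4.0050, 6.7021, 5.4346, 6.4027, 4.5142,
]
LMM_EXPECTED = {
    "beta_response_tumor": 0.430325,
    "se_tumor": 0.3065380887,
    "df_tumor": 8.335249019,
    "p_tumor": 0.1965148824,
    "beta_response_stroma": 0.297375,
    "se_stroma": 0.3065380887,
    "df_stroma": 8.335249019,
    "p_stroma": 0.3592979853,
    "beta_interaction": 0.13295,
    "se_interaction": 0.2516319452,
    "df_interaction": 6.0,
    "p_interaction": 0.6162187182,
    "sigma_patient2": 0.12461256377,
    "sigma_resid2": 0.06331863583,
}


def _lmm_fixture():
    rows = []
    for i in range(8):
        resp = cs.RESPONDER if i < 4 else cs.NON_RESPONDER
        for comp in ("tumor", "stroma"):
            rows.append((f"p{i}_{comp[0].upper()}", f"p{i}", comp, resp))
    meta = pd.DataFrame(
        rows, columns=["segment_id", "patient_id", "compartment", "response"]
    ).set_index("segment_id")
    y = pd.Series(LMM_VALUES, index=meta.index, name="g1")
    return y, meta


def _simulate_gene_matrix(
    n_patients, n_genes, sigma_u=0.5, noise=0.7, effects=None, seed=0
):
    """Direct gene x segment log2 simulation on a paired design.

    ``effects`` maps gene index -> (tumor_effect, stroma_effect), the
    responder-minus-non-responder difference per compartment.
    """
    rng = np.random.default_rng(seed)
    meta = make_segment_meta(n_patients, seed=seed)
    resp = (meta["response"] == cs.RESPONDER).to_numpy()
    tum = (meta["compartment"] == "tumor").to_numpy()
    u = rng.normal(0, sigma_u, (n_genes, n_patients))
    pat_idx = pd.factorize(meta["patient_id"])[0]
    y = 6.0 + u[:, pat_idx] + 1.0 * tum + rng.normal(0, noise, (n_genes, len(meta)))
    signed = np.where(resp, 0.5, -0.5)
    if effects:
        for g, (et, es) in effects.items():
            y[g] += np.where(tum, et, es) * signed
    expr = pd.DataFrame(y, index=[f"g{i:04d}" for i in range(n_genes)], columns=meta.index)
    return expr, meta


class TestMixedModel:
    def test_matches_frozen_reml_oracle(self):
        y, meta = _lmm_fixture()
        fit = cs.fit_gene_mixed_model(y, meta)
        for key, expected in LMM_EXPECTED.items():
            assert getattr(fit, key) == pytest.approx(expected, rel=1e-5), key
        assert not fit.singular and fit.converged

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(9)
        meta = make_segment_meta(15, seed=9)
        y = rng.normal(0, 1, len(meta)) + np.repeat(rng.normal(0, 0.8, 15), 2)
        X, groups = _meta_design(meta)
        df = pd.DataFrame(
            {
                "y": y,
                "t": X[:, 1],
                "rt": X[:, 2],
                "rs": X[:, 3],
                "patient": groups,
            }
        )
        sm_fit = smf.mixedlm("y ~ t + rt + rs", df, groups=df["patient"]).fit(reml=True)
        fit = cs.fit_gene_mixed_model(pd.Series(y, index=meta.index, name="g"), meta)
        assert fit.beta_response_tumor == pytest.approx(sm_fit.params["rt"], abs=1e-5)
        assert fit.beta_response_stroma == pytest.approx(sm_fit.params["rs"], abs=1e-5)
        assert fit.se_tumor == pytest.approx(sm_fit.bse["rt"], abs=1e-5)
        assert fit.sigma_patient2 == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), abs=1e-4
        )
        assert fit.sigma_resid2 == pytest.approx(sm_fit.scale, abs=1e-4)

    def test_singular_fit_matches_ols(self):
        expr, meta = _simulate_gene_matrix(20, 15, sigma_u=0.0, seed=4)
        fits = cs.fit_all_genes(expr, meta)
        singular = fits[fits["singular"]]
        assert len(singular) > 0
        X, _ = _meta_design(meta)
        for gene in singular.index[:5]:
            beta = np.linalg.lstsq(X, expr.loc[gene].to_numpy(), rcond=None)[0]
            assert singular.loc[gene, "beta_response_tumor"] == pytest.approx(beta[2], abs=1e-6)
            assert singular.loc[gene, "beta_response_stroma"] == pytest.approx(beta[3], abs=1e-6)
        # with no simulated patient effect the fitted component is near zero
        assert fits["sigma_patient2"].median() < 0.05

    def test_planted_tumor_effect_recovered(self):
        expr, meta = _simulate_gene_matrix(
            50, 10, sigma_u=0.5, noise=0.3, effects={0: (2.0, 0.0)}, seed=5
        )
        fits = cs.fit_all_genes(expr, meta)
        assert fits.iloc[0]["beta_response_tumor"] == pytest.approx(2.0, abs=0.4)
        assert fits.iloc[0]["p_tumor"] < 1e-6
        assert fits.iloc[0]["p_stroma"] > 0.05

    def test_opposing_effect_gives_interaction(self):
        expr, meta = _simulate_gene_matrix(
            50, 10, sigma_u=0.5, noise=0.3, effects={0: (1.5, -1.5)}, seed=6
        )
        fits = cs.fit_all_genes(expr, meta)
        assert fits.iloc[0]["beta_interaction"] == pytest.approx(3.0, abs=0.5)

    def test_single_compartment_is_inestimable(self):
        y, meta = _lmm_fixture()
        tum = meta[meta["compartment"] == "tumor"]
        with pytest.raises(DataError, match="compartment"):
            cs.fit_gene_mixed_model(y.loc[tum.index], tum)

    def test_null_calibration_within_compartment(self):
        """On global-null paired data with real patient effects, the
        within-compartment response test rejects at the nominal rate."""
        expr, meta = _simulate_gene_matrix(40, 2000, sigma_u=1.0, noise=0.5, seed=7)
        mixed = cs.fit_all_genes(expr, meta)
        rate_mixed = (mixed["p_tumor"] < 0.05).mean()
        assert 0.03 <= rate_mixed <= 0.07

    def test_ignoring_patient_effect_inflates_pooled_response_test(self):
        """For the compartment-pooled response effect, both segments of a
        patient share the random intercept; treating them as independent
        (plain OLS) inflates the null rejection rate at least 1.5-fold."""
        from scipy import stats as sps

        from crtsig._lmm import PatientBlockLMM

        expr, meta = _simulate_gene_matrix(40, 1500, sigma_u=1.0, noise=0.5, seed=8)
        X, groups = _meta_design(meta)
        lmm = PatientBlockLMM(X, groups)
        c = np.array([0.0, 0.0, 0.5, 0.5])  # response effect averaged over compartments
        n, p = X.shape
        XtX_inv = np.linalg.inv(X.T @ X)
        p_mixed, p_ols = [], []
        for y in expr.to_numpy():
            fit = lmm.fit(y)
            p_mixed.append(lmm.contrast(fit, c, y)[3])
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / (n - p)
            se = np.sqrt(s2 * (c @ XtX_inv @ c))
            p_ols.append(2 * sps.t.sf(abs(c @ beta) / se, n - p))
        rate_mixed = float(np.mean(np.array(p_mixed) < 0.05))
        rate_ols = float(np.mean(np.array(p_ols) < 0.05))
        assert 0.02 <= rate_mixed <= 0.08
        assert rate_ols >= 1.5 * rate_mixed


class TestBhAdjust:
    def test_known_values(self):
        assert cs.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert cs.bh_adjust([0.42]) == pytest.approx([0.42])
        assert cs.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_brute_force_step_up_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=37)
        q = cs.bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            expected[idx] = min(
                min(p[j] * m / (list(order).index(j) + 1) for j in order[rank - 1:]), 1.0
            )
        assert q == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = cs.bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert q == pytest.approx(q_sm, abs=1e-12)

    def test_monotone_and_bounds(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        q = cs.bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        with pytest.raises(DataError):
            cs.bh_adjust([0.5, 1.5])


class TestClassification:
    def _fits(self, qt, qs, qi, bt, bs):
        return pd.DataFrame(
            {
                "q_tumor": [qt],
                "q_stroma": [qs],
                "q_interaction": [qi],
                "beta_response_tumor": [bt],
                "beta_response_stroma": [bs],
            },
            index=["g"],
        )

    @pytest.mark.parametrize(
        "qt,qs,qi,bt,bs,expected",
        [
            (0.01, 0.8, 0.5, 1.0, 0.2, "tumor_only"),
            (0.8, 0.01, 0.5, 0.2, 1.0, "stroma_only"),
            (0.01, 0.01, 0.5, 1.0, 0.8, "both"),
            (0.01, 0.01, 0.01, 1.0, -0.8, "opposing"),
            (0.3, 0.3, 0.01, 1.0, -1.0, "opposing"),
            (1.0, 1.0, 1.0, 0.5, 0.5, "none"),
        ],
    )
    def test_rules(self, qt, qs, qi, bt, bs, expected):
        cats = cs.classify_compartment_genes(self._fits(qt, qs, qi, bt, bs))
        assert cats["g"] == expected

    def test_missing_columns_rejected(self):
        with pytest.raises(DataError):
            cs.classify_compartment_genes(pd.DataFrame({"q_tumor": [0.1]}))


class TestConsensus:
    def test_intersection_helper(self):
        counts, consensus = intersect_runs([{"a", "b"}, {"a", "b"}, {"a", "b"}])
        assert consensus == {"a", "b"} and counts["a"] == 3
        _, empty = intersect_runs([{"a"}, {"b"}, {"c"}])
        assert empty == set()

    def test_bootstrap_recovers_strong_markers(self):
        expr, meta = _simulate_gene_matrix(
            30, 12, sigma_u=0.5, noise=0.4,
            effects={0: (2.0, 2.0), 1: (2.5, 0.0)}, seed=11,
        )
        table = cs.bootstrap_consensus(expr, meta, n_runs=5, seed=12)
        assert bool(table.loc["g0000", "in_consensus"])
        assert bool(table.loc["g0001", "in_consensus"])
        assert table["n_runs_significant"].between(0, 5).all()

    def test_deterministic_given_seed(self):
        expr, meta = _simulate_gene_matrix(16, 6, effects={0: (2.0, 2.0)}, seed=13)
        a = cs.bootstrap_consensus(expr, meta, n_runs=3, seed=5)
        b = cs.bootstrap_consensus(expr, meta, n_runs=3, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestPseudoBulk:
    def _meta(self, nuclei):
        meta = make_segment_meta(len(nuclei), seed=1)
        for i, (nt, ns) in enumerate(nuclei):
            meta.loc[f"p{i:03d}_T", "nuclei"] = nt
            meta.loc[f"p{i:03d}_S", "nuclei"] = ns
        return meta

    def test_weighted_mean_arithmetic(self):
        meta = self._meta([(300, 100), (500, 500)])
        counts = pd.DataFrame(
            {"p000_T": [12.0], "p000_S": [4.0], "p001_T": [10.0], "p001_S": [20.0]},
            index=["g0"],
        ).loc[:, meta.index]
        pb, weights = cs.make_pseudobulk(counts, meta)
        assert pb.loc["g0", "p000"] == pytest.approx(np.log2(10.0 + 1))
        assert pb.loc["g0", "p001"] == pytest.approx(np.log2(15.0 + 1))
        assert weights["p000"] == 400

    def test_single_compartment_passthrough(self):
        meta = self._meta([(500, 0)])
        counts = pd.DataFrame({"p000_T": [8.0], "p000_S": [100.0]}, index=["g0"])
        pb, _ = cs.make_pseudobulk(counts.loc[:, meta.index], meta)
        assert pb.loc["g0", "p000"] == pytest.approx(np.log2(9.0))
        solo_meta = meta.loc[["p000_T"]]
        pb2, _ = cs.make_pseudobulk(counts[["p000_T"]], solo_meta)
        assert pb2.loc["g0", "p000"] == pytest.approx(np.log2(9.0))

    def test_zero_total_nuclei_rejected(self):
        meta = self._meta([(0, 0)])
        counts = pd.DataFrame({"p000_T": [8.0], "p000_S": [1.0]}, index=["g0"])
        with pytest.raises(DataError, match="nuclei"):
            cs.make_pseudobulk(counts.loc[:, meta.index], meta)


def test_pseudobulk_auc_between_compartment_aucs(planted_bulk):
    """When the tumor compartment carries the bulk-planted signal, the bulk
    signature scores tumor-only profiles best, stroma-only worst, and the
    nuclei-weighted pseudo-bulk in between."""
    hm, truth = planted_bulk
    genes = truth["gene_id"].tolist()
    mask = hm.samples["response"].isin([cs.RESPONDER, cs.NON_RESPONDER])
    model = cs.fit_signature_model(
        hm.matrix.loc[:, hm.samples.index[mask]],
        genes,
        hm.samples.loc[mask, "response"],
        seed=3,
        params={"lambda": 1.0},
    )
    planted = tuple((int(g[1:]), lfc) for g, lfc in zip(truth["gene_id"], truth["lfc"]))
    cfg = cs.SpatialSimConfig(
        n_patients=60, targets=600, planted_tumor_genes=planted, seed=21
    )
    exp, _ = cs.generate_spatial_cohort(cfg)
    gm = cs.aggregate_targets(exp)
    log2x = np.log2(gm.counts + 1.0)
    meta = gm.segments
    resp = meta.groupby("patient_id")["response"].first()
    y = (resp == cs.RESPONDER).to_numpy()

    def standardized_auc(matrix):
        z = matrix.sub(matrix.mean(axis=1), axis=0).div(
            matrix.std(axis=1, ddof=1), axis=0
        )
        scores = cs.score_samples(model, z)
        return cs.compute_auc(scores.loc[resp.index].to_numpy(), y)

    by_comp = {}
    for comp in ("tumor", "stroma"):
        cols = meta.index[meta["compartment"] == comp]
        block = log2x.loc[:, cols]
        block.columns = meta.loc[cols, "patient_id"]
        by_comp[comp] = standardized_auc(block)
    pb, _ = cs.make_pseudobulk(gm.counts, meta)
    auc_pb = standardized_auc(pb)
    assert by_comp["tumor"] > by_comp["stroma"] + 0.1
    assert by_comp["stroma"] - 0.05 <= auc_pb <= by_comp["tumor"] + 0.05
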