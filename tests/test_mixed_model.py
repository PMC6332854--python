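"""GRM construction, REML pre-adjustment and per-predictor mixed-model tests."""

import numpy as np
import pytest

from hapgwas.mixed_model import (
    GRM,
    NullModelFit,
    compute_grm,
    fit_null,
    preadjust_phenotype,
    test_predictor as predictor_test,
    test_predictors as predictors_test,
)
from tests.conftest import make_geno


def identity_null(y, ve=None):
    """NullModelFit for G = I, lambda = 0: reduces GLS to OLS."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    return NullModelFit(vg=0.0, ve=float(np.var(y, ddof=1)) if ve is None else ve,
                        lam=0.0, loglik=0.0, eigvals=np.ones(n), eigvecs=np.eye(n),
                        y_rot=y.copy())


class TestGRM:
    def test_identical_samples_share_relationship(self):
        rng = np.random.default_rng(0)
        hap_one = rng.integers(0, 2, size=(2, 60)).astype(np.int8)
        hap = np.vstack([hap_one, hap_one, rng.integers(0, 2, size=(2, 60))]).astype(np.int8)
        poly = np.flatnonzero(hap.mean(axis=0) % 1 != 0)  # drop chance-monomorphic columns
        g = compute_grm(make_geno(hap[:, poly]))
        assert g.matrix[0, 1] == pytest.approx(g.matrix[0, 0])
        assert g.matrix[0, 1] == pytest.approx(g.matrix[1, 1])

    def test_unrelated_panel_moments(self):
        rng = np.random.default_rng(1)
        n, m = 150, 5000
        freq = rng.uniform(0.1, 0.9, size=m)
        hap = (rng.random((2 * n, m)) < freq).astype(np.int8)
        g = compute_grm(make_geno(hap))
        d = np.diag(g.matrix)
        off = g.matrix[np.triu_indices(n, 1)]
        assert abs(d.mean() - 1.0) < 0.05
        assert abs(off.mean()) < 0.05

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        hap = (rng.random((20, 200)) < 0.4).astype(np.int8)
        geno = make_geno(hap)
        g = compute_grm(geno).matrix
        perm = rng.permutation(10)
        g2 = compute_grm(geno.take_samples(perm)).matrix
        assert np.allclose(g2, g[np.ix_(perm, perm)])

    def test_monomorphic_errors(self):
        hap = np.zeros((6, 4), dtype=np.int8)
        hap[:, 0] = [0, 1, 0, 1, 1, 0]
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(make_geno(hap))

    def test_psd_up_to_tolerance(self):
        rng = np.random.default_rng(3)
        hap = (rng.random((60, 400)) < rng.uniform(0.1, 0.9, 400)).astype(np.int8)
        g = compute_grm(make_geno(hap))
        d, _ = g.eigendecompose()
        assert d.min() >= 0.0


class TestPreadjust:
    def _grm_identity(self, n):
        return GRM(matrix=np.eye(n), samples=[f"s{i}" for i in range(n)], m=1)

    def test_single_cg_constant_age_subtracts_mean(self):
        rng = np.random.default_rng(4)
        y = rng.normal(5.9, 1.8, size=30)
        y_adj, est = preadjust_phenotype(y, np.zeros(30, dtype=int), np.full(30, 691.0),
                                         self._grm_identity(30))
        assert np.allclose(y_adj, y - y.mean())

    def test_planted_cg_offsets_match_ols(self):
        rng = np.random.default_rng(5)
        n = 200
        cg = rng.integers(0, 2, size=n)
        age = rng.normal(691, 102, size=n)
        y = 5.9 + 0.5 * (cg == 1) + rng.normal(0, 0.3, size=n)
        y_adj, est = preadjust_phenotype(y, cg, age, self._grm_identity(n))
        # with G = I the REML/GLS fit equals OLS: compare to lstsq closed form
        X = np.column_stack([np.ones(n), cg == 1, age - age.mean()])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        est_map = dict(zip(est["term"], est["estimate"]))
        assert est_map["cg[1]"] == pytest.approx(beta[1], abs=1e-8)
        assert abs(est_map["cg[1]"] - 0.5) < 0.15  # within ~2 SE of the planted offset

    def test_planted_age_slope_recovered(self, small_study):
        cfg, geno, phen, truth = small_study
        grm = compute_grm(geno)
        y_adj, est = preadjust_phenotype(phen["wbsf_kg"].to_numpy(), phen["cg"].to_numpy(),
                                         phen["age_days"].to_numpy(), grm)
        slope = float(est.loc[est["term"] == "age_slope", "estimate"].iloc[0])
        # planted 0.002 kg/day; SE at n=500 with trait SD 1.8 is ~0.0008
        assert abs(slope - cfg.age_slope) < 2 * 0.001
        assert abs(np.mean(y_adj)) < 0.05

    def test_small_cg_rejected(self):
        y = np.zeros(10)
        cg = np.array([0] * 8 + [1] * 2)  # group 1 has 2 < 3 records
        with pytest.raises(ValueError, match="< 3 records"):
            preadjust_phenotype(y, cg, np.arange(10.0), self._grm_identity(10))

    def test_confounded_design_rejected(self):
        n = 12
        cg = np.repeat([0, 1, 2, 3], 3)
        age = cg * 10.0  # age is a deterministic function of CG
        with pytest.raises(ValueError, match="collinear"):
            preadjust_phenotype(np.zeros(n), cg, age, self._grm_identity(n))


class TestFitNull:
    def test_identity_grm_boundary_warning(self, caplog):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, size=80)
        grm = GRM(matrix=np.eye(80), samples=[str(i) for i in range(80)], m=1)
        fit = fit_null(y, grm)
        assert fit.boundary  # Vg/Ve unidentifiable when G = I

    def test_scale_equivariance(self, small_study):
        _, geno, phen, _ = small_study
        grm = compute_grm(geno)
        y = phen["wbsf_kg"].to_numpy()
        y = y - y.mean()
        f1 = fit_null(y, grm)
        f2 = fit_null(3.0 * y, grm)
        assert f2.vg == pytest.approx(9.0 * f1.vg, rel=1e-3)
        assert f2.ve == pytest.approx(9.0 * f1.ve, rel=1e-3)
        assert f2.lam == pytest.approx(f1.lam, rel=1e-3)


class TestPredictorTests:
    def test_ols_oracle_with_identity_covariance(self):
        rng = np.random.default_rng(7)
        n = 120
        x = rng.integers(0, 3, size=n).astype(float)
        y = 0.4 * x + rng.normal(0, 1, size=n)
        null = identity_null(y)
        res = predictor_test(x, null)
        slope = np.polyfit(x, y, 1)[0]
        assert res.effect == pytest.approx(slope, abs=1e-8)

    def test_allele_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        n = 100
        x = rng.integers(0, 3, size=n).astype(float)
        y = rng.normal(0, 1, size=n)
        null = identity_null(y)
        r1 = predictor_test(x, null)
        r2 = predictor_test(2.0 - x, null)
        assert r2.effect == pytest.approx(-r1.effect, abs=1e-12)
        assert r2.se == pytest.approx(r1.se, abs=1e-12)
        assert r2.pvalue == pytest.approx(r1.pvalue, abs=1e-12)

    def test_constant_dosage_rejected_single_and_nan_batch(self):
        y = np.arange(10.0)
        null = identity_null(y)
        with pytest.raises(ValueError, match="constant dosage"):
            predictor_test(np.ones(10), null)
        eff, se, pv = predictors_test(np.column_stack([np.ones(10), y]), null)
        assert np.isnan(eff[0]) and np.isfinite(eff[1])

    def test_batch_matches_single(self):
        rng = np.random.default_rng(9)
        n = 80
        X = rng.integers(0, 3, size=(n, 5)).astype(float)
        y = rng.normal(0, 1, size=n)
        null = identity_null(y)
        eff, se, pv = predictors_test(X, null)
        for j in range(5):
            r = predictor_test(X[:, j], null)
            assert eff[j] == pytest.approx(r.effect)
            assert se[j] == pytest.approx(r.se)

    def test_locus_dosages_sum_to_constant_two(self, small_study):
        """The k dosage columns of a locus sum to 2, so a joint fit with an
        intercept is singular — one-vs-rest is the estimable parametrization."""
        from hapgwas.windows import build_windows, enumerate_locus
        _, geno, _, _ = small_study
        locus = enumerate_locus(geno, build_windows(geno, 3).windows[0])
        total = locus.dosage.sum(axis=1)
        assert (total == 2).all()
        X = np.column_stack([np.ones(geno.n_samples), locus.dosage])
        assert np.linalg.matrix_rank(X) < X.shape[1]

    def test_planted_typed_snp_effect_recovered(self, small_study):
        cfg, geno, phen, truth = small_study
        grm = compute_grm(geno)
        y_adj, _ = preadjust_phenotype(phen["wbsf_kg"].to_numpy(), phen["cg"].to_numpy(),
                                       phen["age_days"].to_numpy(), grm)
        null = fit_null(y_adj, grm)
        q = truth.qtls[truth.qtls["typed"]].iloc[0]
        var = geno.variants
        j = int(np.flatnonzero((var["chrom"] == q["chrom"]).to_numpy()
                               & (var["pos"] == q["pos"]).to_numpy())[0])
        gt = geno.genotype_matrix()
        res = predictor_test(gt[:, j], null, predictor=var.loc[j, "id"])
        assert abs(res.effect - q["effect"]) < 2 * res.se
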