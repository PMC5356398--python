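import numpy as np
import pytest
from sklearn.base import clone

from coldnet.netinfer import (
    NetworkALS,
    PriorNetwork,
    als_fit,
    edge_pvalues,
    elastic_net_refine,
    enet_solve,
    init_activity,
    init_connectivity,
)
from coldnet.simulate import GenConfig, generate_truth


def _bare_instance(seed, n=60, k=5, noise=0.0):
    cfg = GenConfig(
        n_genes=n, n_tfs=k, seed=seed, noise_sd=noise,
        n_conserved=0, n_divergent=0, n_path_genes=0, include_tf_rows=False,
    )
    truth = generate_truth(cfg)
    a = truth.true_lambda.T @ truth.true_f
    prior = PriorNetwork(truth.tf_ids, truth.gene_ids, np.sign(truth.true_lambda).astype(np.int8))
    return truth, a, prior


class TestInitConnectivity:
    def test_literature_beats_expression_sign(self):
        # gene g2 perfectly anti-correlated with TF row, but prior says +1
        values = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        gene_ids = ["tf1", "g2"]
        prior = PriorNetwork.from_edges([("tf1", "g2", +1)], ["tf1"], ["g2"])
        lam0 = init_connectivity(prior, values, gene_ids, 0.9)
        assert lam0[1, 0] == 1

    def test_threshold_one_keeps_only_perfect_correlation(self):
        rng = np.random.default_rng(0)
        values = np.vstack([
            np.arange(6.0),                 # tf1
            2 * np.arange(6.0) + 3,         # perfectly correlated
            rng.normal(0, 1, 6),            # not
        ])
        prior = PriorNetwork.empty(["tf1"], ["a", "b", "c"])
        lam0 = init_connectivity(prior, values, ["tf1", "b", "c"], 1.0)
        assert lam0[1, 0] == 1 and lam0[2, 0] == 0

    def test_zero_variance_tf_excluded_with_warning(self):
        values = np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        prior = PriorNetwork.empty(["tf1"], [])
        with pytest.warns(UserWarning, match="zero-variance"):
            lam0 = init_connectivity(prior, values, ["tf1", "g2"], 0.5)
        assert (lam0 == 0).all()

    def test_absent_tf_contributes_prior_only(self):
        values = np.array([[1.0, 2.0, 3.0]])
        prior = PriorNetwork.from_edges([("tfX", "g1", -1)], ["tfX"], ["g1"])
        lam0 = init_connectivity(prior, values, ["g1"], 0.8)
        assert lam0[0, 0] == -1


class TestInitActivity:
    def test_exact_single_tf_solve(self):
        lam0 = np.ones((2, 1))
        a = np.array([[2.0, 4.0], [2.0, 4.0]])
        f = init_activity(lam0, a, ridge=0.0)
        assert np.allclose(f, [[2.0, 4.0]])

    def test_huge_ridge_shrinks_to_zero(self):
        lam0 = np.ones((3, 2))
        a = np.random.default_rng(0).normal(0, 1, (3, 4))
        f = init_activity(lam0, a, ridge=1e12)
        assert np.abs(f).max() < 1e-9

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        lam0 = rng.choice([-1, 0, 1], size=(20, 4))
        a = rng.normal(0, 1, (20, 10))
        ridge = 0.3
        f = init_activity(lam0, a, ridge)
        oracle = np.linalg.inv(lam0.T @ lam0 + ridge * np.eye(4)) @ lam0.T @ a
        assert np.allclose(f, oracle, atol=1e-8)

    def test_all_zero_support_rejected(self):
        with pytest.raises(ValueError):
            init_activity(np.zeros((3, 2)), np.zeros((3, 4)))


class TestAlsFit:
    def test_noise_free_reaches_tiny_residual(self):
        _, a, prior = _bare_instance(0)
        lam, f, trace, converged, _ = als_fit(a, prior.matrix.T, ridge=1e-6)
        rel = ((a - lam @ f) ** 2).sum() / (a**2).sum()
        assert rel < 1e-6 and converged

    def test_large_epsilon_stops_after_one_iteration(self):
        _, a, prior = _bare_instance(1)
        *_, n_iter = als_fit(a, prior.matrix.T, epsilon=1e12)
        assert n_iter == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_non_increasing_every_half_step(self, seed):
        _, a, prior = _bare_instance(seed, noise=0.3)
        *_, trace, _, _ = als_fit(a, prior.matrix.T, ridge=1e-3)[:5]
        lam, f, trace, _, _ = als_fit(a, prior.matrix.T, ridge=1e-3)
        assert all(trace[i + 1] <= trace[i] + 1e-9 for i in range(len(trace) - 1))

    def test_unit_rms_scale_convention(self):
        _, a, prior = _bare_instance(2)
        lam, f, *_ = als_fit(a, prior.matrix.T)
        rms = np.sqrt((f**2).mean(axis=1))
        assert np.allclose(rms[rms > 1e-12], 1.0)

    def test_product_invariant_to_scale_convention(self):
        # Lambda F must equal the unscaled factorization's product
        _, a, prior = _bare_instance(3)
        lam, f, *_ = als_fit(a, prior.matrix.T, ridge=1e-6)
        rel = ((a - lam @ f) ** 2).sum() / (a**2).sum()
        assert rel < 1e-6


class TestElasticNet:
    def test_orthonormal_closed_form(self):
        x = np.zeros((4, 1))
        x[:, 0] = [0.5, 0.5, 0.5, 0.5]  # unit norm
        y = x[:, 0] * 1.0               # OLS coefficient exactly 1.0
        coef = enet_solve(x, y, l1=0.3, l2=0.5)
        assert coef[0] == pytest.approx((1.0 - 0.3) / (1 + 0.5), abs=1e-8)

    def test_orthonormal_two_column_soft_threshold(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(0, 1, (8, 2)))
        b_true = np.array([1.2, -0.4])
        y = q @ b_true
        coef = enet_solve(q, y, l1=0.5, l2=0.25)
        expect = np.sign(b_true) * np.maximum(np.abs(b_true) - 0.5, 0) / 1.25
        assert np.allclose(coef, expect, atol=1e-8)

    def test_zero_penalty_matches_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (20, 3))
        y = rng.normal(0, 1, 20)
        coef = enet_solve(x, y, 0.0, 0.0)
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert np.allclose(coef, ols, atol=1e-6)

    def test_huge_penalty_zeroes_everything(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (20, 3))
        y = rng.normal(0, 1, 20)
        assert np.allclose(enet_solve(x, y, 1e6, 1e6), 0.0)

    def test_refine_skips_single_tf_genes_with_warning(self):
        lam = np.array([[1.0, 0.0], [0.5, -0.5]])
        f = np.random.default_rng(4).normal(0, 1, (2, 12))
        a = lam @ f
        with pytest.warns(UserWarning, match="skipped"):
            out = elastic_net_refine(lam, f, a, enet_lambda=0.01)
        assert out[0, 0] == lam[0, 0]  # kept as-is


class TestEdgePvalues:
    def test_permutation_formula_floor(self):
        # strong single-TF signal: observed beats every permutation
        rng = np.random.default_rng(0)
        f = rng.normal(0, 1, (1, 40))
        lam = np.array([[2.0]])
        a = lam @ f
        p = edge_pvalues(lam, f, a, n_permutations=999, seed=1)
        assert p[0, 0] == pytest.approx(1 / 1000)

    def test_zero_coefficient_gets_p_one(self):
        f = np.random.default_rng(1).normal(0, 1, (2, 30))
        lam = np.array([[1.0, 0.0]])
        a = lam @ f
        # default support skips zero weights entirely
        p = edge_pvalues(lam, f, a, n_permutations=99, seed=0)
        assert np.isnan(p[0, 1])
        # explicit support: a zero coefficient is never significant
        p2 = edge_pvalues(lam, f, a, n_permutations=99, seed=0,
                          support=np.array([[True, True]]))
        assert p2[0, 1] == 1.0

    def test_too_few_permutations_rejected(self):
        f = np.ones((1, 10))
        with pytest.raises(ValueError, match="19"):
            edge_pvalues(np.ones((1, 1)), f, np.ones((1, 10)), n_permutations=10)

    def test_t_approx_agrees_with_permutation_on_gaussian_data(self):
        rng = np.random.default_rng(5)
        f = rng.normal(0, 1, (2, 60))
        lam_true = np.array([[0.35, 0.0], [0.0, 0.5]])
        a = lam_true @ f + rng.normal(0, 1.0, (2, 60))
        lam_fit = np.zeros((2, 2))
        for g in range(2):
            lam_fit[g] = np.linalg.lstsq(f.T, a[g], rcond=None)[0]
        p_perm = edge_pvalues(lam_fit, f, a, n_permutations=4999, seed=2)
        p_t = edge_pvalues(lam_fit, f, a, method="t-approx")
        assert np.nanmax(np.abs(p_perm - p_t)) < 0.02


class TestNetworkALSEstimator:
    def test_sklearn_clone_and_params(self):
        est = NetworkALS(ridge=0.1, p0=0.01)
        cloned = clone(est)
        assert cloned.get_params()["ridge"] == 0.1
        est.set_params(epsilon=1e-4)
        assert est.get_params()["epsilon"] == 1e-4

    @pytest.mark.parametrize("bad", [dict(p0=1.5), dict(epsilon=0.0), dict(enet_alpha=2.0)])
    def test_invalid_params_rejected_at_fit(self, bad):
        truth, a, prior = _bare_instance(0, n=20, k=3)
        with pytest.raises(ValueError):
            NetworkALS(**bad).fit(a, prior=prior, gene_ids=truth.gene_ids)

    def test_noise_free_exact_support_recovery(self):
        truth, a, prior = _bare_instance(7, n=80, k=6)
        m = NetworkALS(center=False, seed=7).fit(a, prior=prior, gene_ids=truth.gene_ids)
        assert set(zip(*np.nonzero(m.connectivity_))) == set(
            zip(*np.nonzero(truth.true_lambda.T))
        )
        assert (m.residual_**2).sum() / (a**2).sum() < 1e-6

    def test_edges_table_consistent(self):
        truth, a, prior = _bare_instance(8, n=40, k=4)
        m = NetworkALS(center=False, seed=8).fit(a, prior=prior, gene_ids=truth.gene_ids)
        edges = m.edges()
        assert (edges["sign"] == np.sign(edges["weight"])).all()
        assert ((edges["pvalue"] > 0) & (edges["pvalue"] < m.p0)).all()
        assert set(edges["tf"]) <= set(truth.tf_ids)

    def test_support_never_leaves_candidates(self):
        truth, a, prior = _bare_instance(9, n=50, k=5, noise=0.2)
        m = NetworkALS(seed=9).fit(a, prior=prior, gene_ids=truth.gene_ids)
        assert not np.any((m.connectivity_ != 0) & ~m.candidate_support_)
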