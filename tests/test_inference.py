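import numpy as np
import pandas as pd
import pytest

from treede.hierarchy import CellTypeTree, TreeNode
from treede.inference import (
    GeneModelFits,
    TypeFit,
    call_de_genes,
    compute_posteriors,
    config_loglik,
    fit_gene_models,
)
from treede.types import DesignInfo, PseudoBulkSet

from conftest import brute_force_posteriors


def _pb(Y_by_type: dict, design: DesignInfo) -> PseudoBulkSet:
    genes = [f"g{i}" for i in range(next(iter(Y_by_type.values())).shape[0])]
    Y = {
        k: pd.DataFrame(v, index=genes, columns=design.subjects)
        for k, v in Y_by_type.items()
    }
    raw = {k: np.exp(f) for k, f in Y.items()}
    return PseudoBulkSet(raw=raw, design=design, Y=Y)


def _design(n_per=5, q=0, seed=3):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    return DesignInfo(
        subjects=[f"s{i}" for i in range(n)],
        A=np.repeat([0.0, 1.0], n_per),
        C=rng.normal(size=(n, q)) if q else None,
    )


def _manual_fits(rng, G, types, priors_tree):
    """Random synthetic per-type log-likelihoods wrapped as GeneModelFits."""
    fits = {}
    for k in types:
        ll0 = rng.normal(-30, 5, size=G)
        ll1 = ll0 + rng.normal(0, 3, size=G)
        fits[k] = TypeFit(
            cell_type=k,
            n_subjects=10,
            mu0=np.zeros(G),
            mu1=np.zeros(G),
            beta0=np.zeros((G, 0)),
            beta1=np.zeros((G, 0)),
            delta=rng.normal(size=(G, 1)),
            sigma2_0=np.ones(G),
            sigma2_1=np.ones(G),
            loglik0=ll0,
            loglik1=ll1,
        )
    return GeneModelFits(fits=fits, gene_ids=np.array([f"g{i}" for i in range(G)]))


class TestFitGeneModels:
    def test_normal_equation_oracle(self):
        """OLS coefficients/variance equal an explicit normal-equations solve."""
        rng = np.random.default_rng(8)
        design = _design(n_per=6, q=1)
        Y = rng.normal(size=(40, 12))
        fits = fit_gene_models(_pb({"A": Y}, design))
        tf = fits.fits["A"]
        X1 = np.column_stack([np.ones(12), design.C, design.A])
        for g in (0, 7, 39):
            beta = np.linalg.solve(X1.T @ X1, X1.T @ Y[g])
            assert tf.mu1[g] == pytest.approx(beta[0], rel=1e-9)
            assert tf.beta1[g, 0] == pytest.approx(beta[1], rel=1e-9)
            assert tf.delta[g, 0] == pytest.approx(beta[2], rel=1e-9)
            rss = ((Y[g] - X1 @ beta) ** 2).sum()
            assert tf.sigma2_1[g] == pytest.approx(rss / 12, rel=1e-9)

    def test_perfect_linear_fit_hits_variance_floor(self):
        design = _design(n_per=3)
        Y = np.tile(2.0 * design.A[:, 0], (3, 1))  # exactly linear in A
        fits = fit_gene_models(_pb({"A": Y}, design))
        tf = fits.fits["A"]
        np.testing.assert_allclose(tf.delta[:, 0], 2.0, rtol=1e-9)
        np.testing.assert_allclose(tf.sigma2_1, 1e-8, rtol=1e-12)
        assert np.isfinite(tf.loglik1).all()

    def test_orthogonal_factor_gives_zero_delta(self):
        design = _design(n_per=4)
        rng = np.random.default_rng(9)
        base = rng.normal(size=(5, 4))
        Y = np.concatenate([base, base], axis=1)  # identical groups
        fits = fit_gene_models(_pb({"A": Y}, design))
        tf = fits.fits["A"]
        np.testing.assert_allclose(tf.delta[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(tf.loglik1, tf.loglik0, rtol=1e-12)

    def test_alternative_never_below_null(self, rng):
        design = _design(n_per=6)
        Y = rng.normal(size=(100, 12))
        fits = fit_gene_models(_pb({"A": Y}, design))
        tf = fits.fits["A"]
        assert (tf.loglik1 >= tf.loglik0 - 1e-9).all()

    def test_too_few_subjects_rejected(self):
        design = DesignInfo(["s1", "s2"], [0.0, 1.0])
        with pytest.raises(ValueError, match="subjects"):
            fit_gene_models(_pb({"A": np.zeros((4, 2))}, design))


class TestConfigLoglik:
    def test_additivity(self, rng):
        tree_types = ["a", "b", "c"]
        fits = _manual_fits(rng, 20, tree_types, None)
        base = config_loglik(fits, [0, 0, 0])
        bumped = config_loglik(fits, [0, 1, 0])
        expect = base + fits.fits["b"].loglik1 - fits.fits["b"].loglik0
        np.testing.assert_allclose(bumped, expect, rtol=1e-12)

    def test_matches_density_product_oracle(self):
        """Config likelihood equals the literal Gaussian density product."""
        from scipy.stats import norm

        rng = np.random.default_rng(10)
        design = _design(n_per=5)
        Y = rng.normal(size=(6, 10))
        pb = _pb({"A": Y, "B": rng.normal(size=(6, 10))}, design)
        fits = fit_gene_models(pb)
        Z = np.array([1, 0])
        got = config_loglik(fits, Z, cell_types=["A", "B"])
        X1 = np.column_stack([np.ones(10), design.A])
        for g in range(6):
            tfA, tfB = fits.fits["A"], fits.fits["B"]
            mA = tfA.mu1[g] + design.A[:, 0] * tfA.delta[g, 0]
            dens = norm.logpdf(Y[g], mA, np.sqrt(tfA.sigma2_1[g])).sum()
            mB = np.full(10, tfB.mu0[g])
            dens += norm.logpdf(
                pb.Y["B"].to_numpy()[g], mB, np.sqrt(tfB.sigma2_0[g])
            ).sum()
            assert got[g] == pytest.approx(dens, rel=1e-9)


class TestPosteriors:
    def test_k1_bayes_rule_closed_form(self, rng):
        tree = CellTypeTree(TreeNode("only", pi=0.3))
        fits = _manual_fits(rng, 30, ["only"], tree)
        inf = compute_posteriors(fits, tree)
        tf = fits.fits["only"]
        l0, l1 = np.exp(tf.loglik0 - tf.loglik0), np.exp(tf.loglik1 - tf.loglik0)
        expect = 0.3 * l1 / (0.3 * l1 + 0.7 * l0)
        np.testing.assert_allclose(inf.posterior["only"].to_numpy(), expect, rtol=1e-10)

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_matches_brute_force_enumeration(self, K, rng):
        """Random priors + likelihoods: exact match with the naive oracle."""
        labels = [f"t{j}" for j in range(K)]
        # random caterpillar tree with random probabilities
        node = TreeNode(labels[0], p=float(rng.uniform(0.2, 0.95)))
        for lab in labels[1:]:
            node = TreeNode(
                children=[node, TreeNode(lab, p=float(rng.uniform(0.2, 0.95)))],
                p=float(rng.uniform(0.2, 0.95)),
            )
        node.p = None
        node.pi = float(rng.uniform(0.2, 0.8))
        tree = CellTypeTree(node)
        fits = _manual_fits(rng, 25, tree.leaves, tree)
        inf = compute_posteriors(fits, tree)
        ll0 = np.column_stack([fits.fits[k].loglik0 for k in tree.leaves])
        ll1 = np.column_stack([fits.fits[k].loglik1 for k in tree.leaves])
        oracle = brute_force_posteriors(tree, ll0, ll1)
        np.testing.assert_allclose(inf.posterior.to_numpy(), oracle, atol=1e-10)

    def test_config_posteriors_sum_to_one(self, chain_tree, rng):
        fits = _manual_fits(rng, 10, chain_tree.leaves, chain_tree)
        inf = compute_posteriors(fits, chain_tree, keep_config=True)
        total = np.exp(inf.config_logjoint - inf.log_marginal[:, None]).sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_flat_likelihood_returns_renormalized_prior(self, chain_tree):
        from treede.priors import configuration_matrix, log_prior_table

        G = 4
        fits = {}
        for k in chain_tree.leaves:
            ll = np.full(G, -12.0)
            fits[k] = TypeFit(
                k, 8, *(np.zeros(G),) * 2, np.zeros((G, 0)), np.zeros((G, 0)),
                np.zeros((G, 1)), np.ones(G), np.ones(G), ll, ll.copy(),
            )
        coll = GeneModelFits(fits=fits, gene_ids=np.array(list("wxyz")))
        inf = compute_posteriors(coll, chain_tree)
        table = np.exp(log_prior_table(chain_tree))
        Zmat = configuration_matrix(3)
        for j, leaf in enumerate(chain_tree.leaves):
            expect = table[Zmat[:, j]].sum() / table.sum()
            np.testing.assert_allclose(
                inf.posterior[leaf].to_numpy(), expect, atol=1e-12
            )

    def test_monotone_in_evidence(self, chain_tree, rng):
        fits = _manual_fits(rng, 1, chain_tree.leaves, chain_tree)
        leaf = chain_tree.leaves[0]
        posts = []
        for bump in (0.0, 1.0, 3.0, 10.0):
            fits.fits[leaf].loglik1 = fits.fits[leaf].loglik0 + bump
            posts.append(
                compute_posteriors(fits, chain_tree).posterior[leaf].iloc[0]
            )
        assert all(b >= a for a, b in zip(posts, posts[1:]))

    def test_numerically_stable_for_huge_loglik_gaps(self, chain_tree):
        G = 2
        fits = {}
        for j, k in enumerate(chain_tree.leaves):
            ll0 = np.array([0.0, -1e4])
            ll1 = np.array([-1e4, 0.0]) if j == 0 else ll0 + 1.0
            fits[k] = TypeFit(
                k, 8, np.zeros(G), np.zeros(G), np.zeros((G, 0)), np.zeros((G, 0)),
                np.zeros((G, 1)), np.ones(G), np.ones(G), ll0, ll1,
            )
        coll = GeneModelFits(fits=fits, gene_ids=np.array(["u", "v"]))
        inf = compute_posteriors(coll, chain_tree)
        assert np.isfinite(inf.posterior.to_numpy()).all()
        assert np.isfinite(inf.log_marginal).all()
        assert inf.posterior.iloc[0, 0] < 1e-100  # overwhelming null evidence
        assert inf.posterior.iloc[1, 0] > 0.5

    def test_kmax_guard(self, rng):
        labels = [f"t{j}" for j in range(5)]
        tree = CellTypeTree(
            TreeNode(children=[TreeNode(l, p=0.5) for l in labels], pi=0.5)
        )
        fits = _manual_fits(rng, 3, labels, tree)
        with pytest.raises(ValueError, match="kmax"):
            compute_posteriors(fits, tree, kmax=4)


class TestCallDeGenes:
    def _inf(self, values):
        from treede.inference import GeneInference

        genes = [f"g{i}" for i in range(len(values))]
        post = pd.DataFrame({"A": values}, index=genes)
        return GeneInference(
            posterior=post,
            log_marginal=np.zeros(len(values)),
            delta=post * 0.0,
            leaf_order=["A"],
        )

    def test_strict_boundary(self):
        inf = self._inf([0.951, 0.95, 0.4])
        called = call_de_genes(inf, cutoff=0.95)["A"]
        assert list(called.index) == ["g0"]  # 0.95 exactly is not called

    def test_tiny_cutoff_calls_all_positive(self):
        inf = self._inf([0.2, 0.0, 0.8])
        called = call_de_genes(inf, cutoff=1e-9)["A"]
        assert set(called.index) == {"g0", "g2"}

    def test_ranked_descending_with_gene_tiebreak(self):
        inf = self._inf([0.97, 0.99, 0.97])
        called = call_de_genes(inf, cutoff=0.9)["A"]
        assert list(called.index) == ["g1", "g0", "g2"]

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            call_de_genes(self._inf([0.5]), cutoff=1.0)


class TestParameterRecovery:
    def test_delta_unbiased_and_power_monotone(self):
        """Data from the model's own Gaussian law: delta recovered, posterior
        power rises monotonically with |delta|/sigma."""
        rng = np.random.default_rng(99)
        design = _design(n_per=10)
        tree = CellTypeTree(TreeNode("only", pi=0.2))
        mean_posts, biases = [], []
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            Y = rng.normal(0.0, 1.0, size=(400, 20)) + delta * design.A[:, 0]
            fits = fit_gene_models(_pb({"only": Y}, design))
            biases.append(fits.fits["only"].delta[:, 0].mean() - delta)
            inf = compute_posteriors(fits, tree)
            mean_posts.append(inf.posterior["only"].mean())
        # unbiasedness within Monte-Carlo error: se(mean delta-hat) =
        # sqrt(sigma^2 * (1/10 + 1/10) / 400) ~ 0.022; allow 3 se
        assert all(abs(b) < 0.07 for b in biases)
        assert all(b > a for a, b in zip(mean_posts, mean_posts[1:]))
        assert mean_posts[-1] > 0.99
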