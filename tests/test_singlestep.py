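"""Single-step system assembly, its Gibbs sampler, the plug-in MME and PCG."""

import numpy as np
import pytest
from scipy import sparse

from ssbayesn import regions as rg
from ssbayesn.mcmc import ChainOptions, FixedVariances
from ssbayesn.regions import derive_priors_multitrait, partition_regions
from ssbayesn.relationship import PedigreeGraph, partition_blocks
from ssbayesn.singlestep import (MmeSystem, PcgError, assemble_mme,
                                 build_ss_system, fullcond_G0,
                                 fullcond_epsilon, gibbs_ssbayesn0,
                                 predict_gebv_singlestep,
                                 predict_gebv_singlestep_chain, run_sssnpblup,
                                 solve_pcg)

from conftest import build_toy_ss


@pytest.fixture(scope="module")
def toy_system(small_dataset):
    return build_toy_ss(small_dataset)


@pytest.fixture(scope="module")
def plugin_solution(toy_system):
    """Dense MME solution with plug-in variances on the toy system."""
    system, blocks, traits = toy_system
    S = system.regions.n_regions
    B = np.broadcast_to(system.priors.snp_scale(), (S, 2, 2)).copy()
    R0 = np.diag(traits.residual_var)
    G0 = np.cov(traits.tbv.T)
    mme = assemble_mme(system, B, G0, R0)
    x = np.linalg.solve(mme.dense(), mme.rhs)
    return system, mme, B, R0, G0, x


class TestBuildSystem:
    def test_record_layout(self, toy_system, small_dataset):
        system, blocks, _ = toy_system
        pop, qtl, traits, genotyped, phenotyped, y_obs = small_dataset
        assert system.n_records == phenotyped.sum()
        assert system.N_n == (~genotyped).sum()
        assert system.W.shape == (system.n_records, system.n_markers)

    def test_contrast_column_is_minus_one_for_genotyped(self, toy_system,
                                                        small_dataset):
        system, _, _ = toy_system
        pop, qtl, traits, genotyped, phenotyped, y_obs = small_dataset
        rec_genotyped = genotyped[system.record_animals]
        assert np.all(system.X[rec_genotyped, 1] == -1.0)
        # non-genotyped contrast is the pedigree regression, not -1
        assert not np.all(system.X[~rec_genotyped, 1] == -1.0)

    def test_imputation_consistency_with_centering(self, toy_system):
        # both blocks centered with the same 2p: column means of M_g are 0
        system, _, _ = toy_system
        assert np.allclose(system.M_g.mean(0), 0.0, atol=1e-12)

    def test_incomplete_record_rejected(self, small_dataset):
        pop, qtl, traits, genotyped, phenotyped, y_obs = small_dataset
        bad = y_obs.copy()
        i = np.flatnonzero(phenotyped)[0]
        bad[i, 0] = np.nan  # one trait missing for a phenotyped animal
        from ssbayesn.relationship import partition_blocks
        ped = PedigreeGraph.from_population(pop)
        blocks = partition_blocks(ped, genotyped)
        keep = qtl.analysis_snps(pop.n_snp)
        M_raw = pop.genotypes[np.ix_(blocks.genotyped_idx, keep)].astype(float)
        rmap = partition_regions(pop.chrom[keep], mode="whole_genome")
        priors = derive_priors_multitrait(np.eye(2), np.eye(2), np.full(
            M_raw.shape[1], 0.4))
        with pytest.raises(ValueError, match="all traits or none"):
            build_ss_system(bad, genotyped, phenotyped, M_raw, blocks, rmap,
                            priors)

    def test_all_genotyped_drops_contrast(self):
        ped = PedigreeGraph([-1, -1, 0], [-1, -1, 1])
        blocks = partition_blocks(ped, np.ones(3, dtype=bool))
        M_raw = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        rmap = partition_regions(np.zeros(2), mode="whole_genome")
        priors = derive_priors_multitrait(np.eye(2), np.eye(2),
                                          np.array([0.25, 0.25]))
        y = np.ones((3, 2))
        system = build_ss_system(y, np.ones(3, bool), np.ones(3, bool),
                                 M_raw, blocks, rmap, priors)
        assert not system.has_mug
        assert system.X.shape[1] == 1


class TestEpsilonConditional:
    def test_tight_prior_shrinks_to_zero(self, toy_system):
        system, _, traits = toy_system
        y_star = system.y.copy()
        mean, _ = fullcond_epsilon(system, y_star, G0=1e-8 * np.eye(2),
                                   R0=np.diag(traits.residual_var))
        assert np.abs(mean).max() < 1e-3

    def test_single_animal_scalar_closed_form(self):
        # one non-genotyped phenotyped offspring of two genotyped founders:
        # precision = 1/sigma_e^2 + a^nn/sigma_g^2, mean = (y/sigma_e^2)/prec
        ped = PedigreeGraph([-1, -1, 0], [-1, -1, 1])
        blocks = partition_blocks(ped, np.array([0, 1]))
        M_raw = np.array([[2.0], [0.0]])
        rmap = partition_regions(np.zeros(1), mode="whole_genome")
        priors = rg.derive_priors_singletrait(1.0, 1.0, np.array([0.5]))
        y = np.array([[np.nan], [np.nan], [1.2]])
        phen = np.array([False, False, True])
        system = build_ss_system(y, np.array([True, True, False]), phen,
                                 M_raw, blocks, rmap, priors)
        s2e, s2g = 2.0, 0.5
        mean, cov = fullcond_epsilon(system, np.array([[1.2]]),
                                     G0=np.array([[s2g]]),
                                     R0=np.array([[s2e]]))
        a_nn = blocks.Ainv_nn.toarray()[0, 0]  # = 2 for the trio
        prec = 1 / s2e + a_nn / s2g
        assert mean[0] == pytest.approx((1.2 / s2e) / prec)
        assert cov[0, 0] == pytest.approx(1 / prec)

    def test_isolated_unphenotyped_founder_mean_zero(self):
        # founder 3: not genotyped, not phenotyped, unrelated to everyone
        ped = PedigreeGraph([-1, -1, 0, -1], [-1, -1, 1, -1])
        blocks = partition_blocks(ped, np.array([0, 1]))
        M_raw = np.array([[2.0], [0.0]])
        rmap = partition_regions(np.zeros(1), mode="whole_genome")
        priors = rg.derive_priors_singletrait(1.0, 1.0, np.array([0.5]))
        y = np.array([[np.nan], [np.nan], [0.7], [np.nan]])
        phen = np.array([False, False, True, False])
        system = build_ss_system(y, np.array([True, True, False, False]),
                                 phen, M_raw, blocks, rmap, priors)
        mean, _ = fullcond_epsilon(system, np.array([[0.7]]),
                                   G0=np.array([[1.0]]),
                                   R0=np.array([[1.0]]))
        iso = list(system.nongenotyped_idx).index(3)
        assert mean[iso] == pytest.approx(0.0, abs=1e-12)


class TestG0Conditional:
    def _priors(self):
        return derive_priors_multitrait(np.eye(2), np.eye(2), np.full(5, 0.5))

    def test_zero_eps(self):
        priors = self._priors()
        Ainn = sparse.eye(4).tocsr()
        df, scale = fullcond_G0(np.zeros((4, 2)), Ainn, priors)
        assert df == priors.nu_G + 4
        assert np.allclose(scale, priors.V_G)

    def test_identity_example(self):
        priors = self._priors()
        priors.V_G = np.zeros((2, 2))
        eps = np.ones((2, 2))
        df, scale = fullcond_G0(eps, sparse.eye(2).tocsr(), priors)
        assert df == priors.nu_G + 2
        assert np.allclose(scale, [[2, 2], [2, 2]])

    def test_random_quadratic_form_oracle(self):
        rng = np.random.default_rng(8)
        n = 12
        Q = rng.standard_normal((n, n))
        Ainn = sparse.csr_matrix(Q @ Q.T + n * np.eye(n))
        eps = rng.standard_normal((n, 2))
        priors = self._priors()
        _, scale = fullcond_G0(eps, Ainn, priors)
        brute = np.array([[eps[:, t] @ (Ainn.toarray() @ eps[:, u])
                           for u in range(2)] for t in range(2)])
        assert np.allclose(scale, brute + priors.V_G)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            fullcond_G0(np.zeros((3, 2)), sparse.eye(2).tocsr(),
                        self._priors())


class TestMme:
    def test_dimension_and_symmetry(self, plugin_solution):
        system, mme, *_ = plugin_solution
        T = 2
        assert mme.dim == T * (2 + system.n_markers + system.N_n)
        C = mme.dense()
        assert np.abs(C - C.T).max() < 1e-10

    def test_reduces_to_snpblup_without_nongenotyped(self):
        rng = np.random.default_rng(9)
        n, k = 25, 8
        ped = PedigreeGraph([-1] * n, [-1] * n)
        blocks = partition_blocks(ped, np.ones(n, dtype=bool))
        M_raw = rng.integers(0, 3, size=(n, k)).astype(float)
        rmap = partition_regions(np.zeros(k), mode="whole_genome")
        p = M_raw.mean(0) / 2
        priors = derive_priors_multitrait(np.eye(2), np.eye(2), p)
        y = rng.standard_normal((n, 2))
        system = build_ss_system(y, np.ones(n, bool), np.ones(n, bool),
                                 M_raw, blocks, rmap, priors)
        B = np.array([np.eye(2) * 0.1])
        mme = assemble_mme(system, B, None, np.eye(2))
        x, _ = solve_pcg(mme, tol=1e-12)
        # direct ridge solve per trait (identity R0 -> traits decouple)
        Mc = system.M_g
        for t in range(2):
            X = np.ones((n, 1))
            C = np.block([[X.T @ X, X.T @ Mc],
                          [Mc.T @ X, Mc.T @ Mc + np.eye(k) / 0.1]])
            rhs = np.concatenate([X.T @ y[:, t], Mc.T @ y[:, t]])
            sol = np.linalg.solve(C, rhs)
            mu, al, _ = mme.split(x)
            assert np.allclose(mu[0, t], sol[0], atol=1e-8)
            assert np.allclose(al[:, t], sol[1:], atol=1e-8)

    def test_nonpd_variances_rejected(self, toy_system):
        system, _, traits = toy_system
        S = system.regions.n_regions
        bad = np.broadcast_to(np.array([[1.0, 2.0], [2.0, 1.0]]),
                              (S, 2, 2)).copy()
        with pytest.raises(ValueError, match="positive definite"):
            assemble_mme(system, bad, np.eye(2), np.eye(2))


class TestPcg:
    def test_identity_system_one_iteration(self):
        mme = MmeSystem(matvec=lambda x: x, diag=np.ones(7),
                        rhs=np.arange(7.0), n_fixed=0, n_markers=0, N_n=0,
                        n_traits=1)
        x, it = solve_pcg(mme, tol=1e-12)
        assert it == 1
        assert np.allclose(x, np.arange(7.0))

    def test_random_spd_matches_dense(self):
        rng = np.random.default_rng(10)
        Q = rng.standard_normal((100, 100))
        A = Q @ Q.T + 100 * np.eye(100)
        b = rng.standard_normal(100)
        mme = MmeSystem(matvec=lambda x: A @ x, diag=np.diag(A).copy(),
                        rhs=b, n_fixed=0, n_markers=0, N_n=0, n_traits=1)
        x, it = solve_pcg(mme, tol=1e-12)
        assert np.abs(x - np.linalg.solve(A, b)).max() <= 1e-8
        assert np.linalg.norm(b - A @ x) / np.linalg.norm(b) <= 1e-12

    def test_max_iter_error_carries_residual(self):
        rng = np.random.default_rng(11)
        Q = rng.standard_normal((50, 50))
        A = Q @ Q.T + np.eye(50)
        mme = MmeSystem(matvec=lambda x: A @ x, diag=np.diag(A).copy(),
                        rhs=rng.standard_normal(50), n_fixed=0, n_markers=0,
                        N_n=0, n_traits=1)
        with pytest.raises(PcgError) as exc:
            solve_pcg(mme, tol=1e-14, max_iter=2)
        assert exc.value.best_residual > 0
        assert exc.value.iterations == 2


class TestPluginEquivalence:
    def test_gibbs_plugin_matches_mme(self, plugin_solution):
        """The module's central oracle: fixed-variance Gibbs posterior means
        equal the direct solution of the single-step equations."""
        system, mme, B, R0, G0, x = plugin_solution
        chain = gibbs_ssbayesn0(system, ChainOptions(n_iter=8000,
                                                     burn_in=2000, thin=2,
                                                     seed=13),
                                fixed_variances=FixedVariances(B=B, R0=R0,
                                                               G0=G0))
        mu_d, al_d, ep_d = mme.split(x)
        assert np.abs(chain.alpha.mean(0) - al_d).max() < 0.05
        g_chain = predict_gebv_singlestep_chain(system, chain)
        g_mme = predict_gebv_singlestep(system, mu_d[1], al_d, ep_d)
        for t in range(2):
            assert np.corrcoef(g_chain[:, t], g_mme[:, t])[0, 1] > 0.99

    def test_sssnpb2_equivalent_to_source_chain(self, toy_system):
        """ssSNPBLUP with (co)variances from a ssBayesN0 chain reproduces
        that chain's breeding values (equivalent models)."""
        system, _, _ = toy_system
        chain = gibbs_ssbayesn0(system, ChainOptions(n_iter=4000,
                                                     burn_in=1500, thin=5,
                                                     seed=14))
        sol = run_sssnpblup(system, chain, varsource="ssbayesn0")
        g_blup = predict_gebv_singlestep(system, sol["mu_star"][1],
                                         sol["alpha"], sol["eps"])
        g_bayes = predict_gebv_singlestep_chain(system, chain)
        for t in range(2):
            assert np.corrcoef(g_blup[:, t], g_bayes[:, t])[0, 1] > 0.99

    def test_varsource_bayesn0_requires_markers(self, toy_system):
        system, _, _ = toy_system
        chain = gibbs_ssbayesn0(system, ChainOptions(n_iter=300, burn_in=100,
                                                     thin=5, seed=15))
        with pytest.raises(ValueError, match="M_for_G0"):
            run_sssnpblup(system, chain, varsource="bayesn0")

    def test_same_seed_identical(self, toy_system):
        system, _, _ = toy_system
        opts = ChainOptions(n_iter=200, burn_in=50, thin=5, seed=16)
        a = gibbs_ssbayesn0(system, opts)
        b = gibbs_ssbayesn0(system, opts)
        assert np.array_equal(a.eps, b.eps)
        assert np.array_equal(a.G0, b.G0)


class TestSsPrediction:
    def test_reduction_without_mug_and_eps(self, toy_system):
        system, _, _ = toy_system
        k = system.n_markers
        alpha = np.random.default_rng(17).standard_normal((k, 2))
        g = predict_gebv_singlestep(system, np.zeros(2), alpha,
                                    np.zeros((system.N_n, 2)))
        M_all = np.vstack([system.M_hat_n, system.M_g])
        assert np.allclose(g, M_all @ alpha)

    def test_genotyped_block_uses_minus_mug(self, toy_system):
        system, _, _ = toy_system
        g = predict_gebv_singlestep(system, np.array([3.0, -1.0]),
                                    np.zeros((system.n_markers, 2)),
                                    np.zeros((system.N_n, 2)))
        assert np.allclose(g[system.N_n:, 0], -3.0)
        assert np.allclose(g[system.N_n:, 1], 1.0)

    def test_eps_added_to_nongenotyped_only(self, toy_system):
        system, _, _ = toy_system
        eps = np.random.default_rng(18).standard_normal((system.N_n, 2))
        g = predict_gebv_singlestep(system, np.zeros(2),
                                    np.zeros((system.n_markers, 2)), eps)
        assert np.allclose(g[:system.N_n], eps)
        assert np.allclose(g[system.N_n:], 0.0)

    def test_missing_eps_rejected(self, toy_system):
        system, _, _ = toy_system
        with pytest.raises(ValueError, match="eps"):
            predict_gebv_singlestep(system, np.zeros(2),
                                    np.zeros((system.n_markers, 2)),
                                    np.zeros((1, 2)))
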