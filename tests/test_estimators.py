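"""Likelihood and maximum-likelihood estimation (root locations, dispersal)."""
import numpy as np
import pytest
from scipy.optimize import minimize

import argbm
from argbm import ARG, BrownianDispersal
from argbm.estimators import fit, log_likelihood, mle_dispersal, mle_root_locations
from argbm.paths import enumerate_all_paths, enumerate_minimal_paths, shared_times
from argbm.simulate import SimConfig, simulate_arg, simulate_conditioned_bm

from conftest import small_sim_arg


def classic_tree_gls(arg, locations):
    """Independent oracle: phylogenetic-BM GLS on a single tree, with shared
    times computed from pairwise MRCAs (no path machinery, plain inverses)."""
    tree = arg.ts.first()
    samples = list(arg.samples)
    root_time = arg.node_times[tree.root]
    n = len(samples)
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s[i, j] = root_time - tree.tmrca(samples[i], samples[j])
    loc = np.asarray(locations, dtype=float)
    if loc.ndim == 1:
        loc = loc[:, None]
    sinv = np.linalg.inv(s)
    one = np.ones((n, 1))
    mu = (one.T @ sinv @ loc) / (one.T @ sinv @ one)
    resid = loc - one @ mu
    disp = resid.T @ sinv @ resid / n
    return mu, disp, s


def two_leaf_tree(t=4.0):
    return ARG.from_structure(
        node_times=[0, 0, t], samples=[0, 1],
        edges=[(0, 2, 0, 1), (1, 2, 0, 1)], sequence_length=1,
    )


class TestTreeCollapse:
    @pytest.mark.parametrize("seed", [2, 5])
    def test_fit_matches_classic_gls(self, seed):
        arg = simulate_arg(
            SimConfig(n_samples=8, recombination_rate=0.0, seed=seed)
        )
        rng = np.random.default_rng(seed)
        loc = rng.normal(size=arg.num_samples)
        res = fit(arg, loc)
        mu, disp, _ = classic_tree_gls(arg, loc)
        assert res.mu_hat[0, 0] == pytest.approx(mu[0, 0], abs=1e-9)
        assert res.dispersal == pytest.approx(disp[0, 0], abs=1e-9)
        assert res.n_paths == res.n_samples
        assert res.n_roots == 1

    def test_two_leaf_closed_form(self):
        # leaves at -a, a with root-to-leaf time t and no shared time:
        # mu_hat = 0 and sigma2_hat = a^2 / t
        a, t = 1.5, 4.0
        res = fit(two_leaf_tree(t), np.array([-a, a]))
        assert res.mu_hat[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert res.dispersal == pytest.approx(a * a / t)

    def test_trivial_bivariate_loglik(self):
        # star tree with unit branch lengths: S = I; at mu=0, sigma2=1 and
        # locations at the mean the log-density is -log(2*pi)
        arg = two_leaf_tree(1.0)
        basis = enumerate_minimal_paths(arg)
        sp = shared_times(arg, basis)
        ll = log_likelihood(
            np.zeros(2), basis, sp, np.array([[0.0]]), np.array([[1.0]])
        )
        assert ll == pytest.approx(-np.log(2 * np.pi))


class TestMLEs:
    def test_mu_hat_matches_numeric_maximization(self, two_tree, two_tree_locations):
        model = BrownianDispersal().fit(two_tree, two_tree_locations)
        basis, sp = model.basis_, model.shared_times_

        def nll(params):
            mu, log_s2 = params
            return -log_likelihood(
                two_tree_locations, basis, sp,
                np.array([[mu]]), np.array([[np.exp(log_s2)]]),
            )

        opt = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options=dict(xatol=1e-9, fatol=1e-12))
        assert model.root_locations_[0, 0] == pytest.approx(opt.x[0], abs=1e-5)
        assert model.dispersal_ == pytest.approx(np.exp(opt.x[1]), rel=1e-4)

    def test_mle_beats_perturbations(self, two_tree, two_tree_locations):
        model = BrownianDispersal().fit(two_tree, two_tree_locations)
        best = model.log_likelihood_
        rng = np.random.default_rng(0)
        for _ in range(100):
            mu = model.root_locations_ + rng.normal(scale=0.3)
            s2 = model.dispersal_ * np.exp(rng.normal(scale=0.3))
            ll = log_likelihood(
                two_tree_locations, model.basis_, model.shared_times_,
                mu, np.array([[s2]]),
            )
            assert ll <= best + 1e-9

    def test_loglik_invariant_to_basis(self, loop_arg):
        loc = np.array([0.3, -0.2])
        minimal = enumerate_minimal_paths(loop_arg)
        full = enumerate_all_paths(loop_arg)
        mu = np.array([[0.1]])
        s2 = np.array([[0.8]])
        ll_min = log_likelihood(loc, minimal, shared_times(loop_arg, minimal), mu, s2)
        ll_full = log_likelihood(loc, full, shared_times(loop_arg, full), mu, s2)
        assert ll_min == pytest.approx(ll_full)

    def test_all_samples_identical_location(self, chopped_sim_arg):
        loc = np.full(chopped_sim_arg.num_samples, 2.5)
        res = fit(chopped_sim_arg, loc)
        assert np.allclose(res.mu_hat, 2.5)
        assert res.dispersal == pytest.approx(0.0, abs=1e-12)

    def test_translation_and_scaling_equivariance(self, chopped_sim_arg):
        rng = np.random.default_rng(3)
        loc = rng.normal(size=chopped_sim_arg.num_samples)
        base = fit(chopped_sim_arg, loc)
        shifted = fit(chopped_sim_arg, loc + 10.0)
        assert np.allclose(shifted.mu_hat, base.mu_hat + 10.0)
        assert shifted.dispersal == pytest.approx(base.dispersal)
        scaled = fit(chopped_sim_arg, 3.0 * loc)
        assert scaled.dispersal == pytest.approx(9.0 * base.dispersal)

    def test_2d_dispersal_matrix_scaling(self, chopped_sim_arg):
        rng = np.random.default_rng(4)
        loc = rng.normal(size=(chopped_sim_arg.num_samples, 2))
        base = fit(chopped_sim_arg, loc)
        assert base.dispersal.shape == (2, 2)
        assert np.allclose(base.dispersal, base.dispersal.T)
        assert np.linalg.eigvalsh(base.dispersal).min() >= 0
        scaled = fit(chopped_sim_arg, 2.0 * loc)
        assert np.allclose(scaled.dispersal, 4.0 * base.dispersal)

    def test_label_invariance(self):
        # the same toy loop ARG with node ids permuted gives identical fits
        arg1 = argbm.examples.two_sample_loop_arg()
        perm = {0: 1, 1: 0, 2: 4, 3: 2, 4: 5, 5: 3}
        # times for relabeled nodes
        times = np.zeros(6)
        for old, new in perm.items():
            times[new] = arg1.node_times[old]
        edges = [
            (perm[c], perm[p], l, r)
            for (c, p), spans in arg1._spans.items()
            for (l, r) in spans
        ]
        arg2 = ARG.from_structure(times, [perm[0], perm[1]], edges, 2)
        loc1 = np.array([0.4, -1.0])
        res1 = fit(arg1, loc1)
        # align locations with the permuted sample ids (sample 0 -> id 1)
        loc2 = np.array([loc1[1], loc1[0]])
        res2 = fit(arg2, loc2)
        assert res2.dispersal == pytest.approx(res1.dispersal)
        assert res2.mu_hat[0, 0] == pytest.approx(res1.mu_hat[0, 0])
        assert res2.loglik == pytest.approx(res1.loglik)


class TestRecoveryAndBias:
    def test_conditioned_data_recovers_dispersal(self):
        # correctly specified model: mean sigma2_hat over replicates is
        # within 3 standard errors of the truth
        sigma2, reps = 1.0, 12
        estimates = []
        for rep in range(reps):
            arg = small_sim_arg(seed=100 + rep, n_samples=20, L=3e4)
            cut = float(np.quantile(arg.node_times[arg.node_times > 0], 0.8)) + 0.5
            chopped = arg.chop(cut)
            draw = simulate_conditioned_bm(
                chopped, dispersal=sigma2, seed=rep, keep_displacements=False
            )
            estimates.append(fit(chopped, draw.sample_locations()).dispersal)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(reps)
        assert abs(mean - sigma2) < 3 * se

    def test_nested_windows_increase_dispersal_on_midpoint_data(self):
        # fixed (model-misspecified) sample locations: adding trees adds
        # loops, which can only increase the implied clustering and hence
        # the fitted dispersal, on average
        from argbm.simulate import simulate_midpoint_bm

        diffs = []
        for rep in range(6):
            arg = small_sim_arg(seed=300 + rep, n_samples=15, L=8e4)
            cut = float(np.quantile(arg.node_times[arg.node_times > 0], 0.7)) + 0.5
            chopped = arg.chop(cut)
            draw = simulate_midpoint_bm(
                chopped, dispersal=1.0, seed=rep, keep_displacements=False
            )
            loc = draw.sample_locations()
            small = fit(chopped.first_trees(1), loc).dispersal
            big = fit(chopped.first_trees(8), loc).dispersal
            diffs.append(big - small)
        assert np.mean(diffs) > 0

    def test_root_variance_relaxation(self, chopped_sim_arg):
        # adding prior variance to freely-estimated root locations cannot
        # move the GLS estimates (it inflates variance only in directions
        # spanned by the root means), but it widens ancestor uncertainty
        rng = np.random.default_rng(9)
        loc = rng.normal(size=chopped_sim_arg.num_samples)
        rigid = BrownianDispersal().fit(chopped_sim_arg, loc)
        relaxed = BrownianDispersal(root_variance=50.0).fit(chopped_sim_arg, loc)
        assert relaxed.dispersal_ == pytest.approx(rigid.dispersal_)
        assert np.allclose(relaxed.root_locations_, rigid.root_locations_)
        sample = int(chopped_sim_arg.samples[0])
        cut = float(chopped_sim_arg.node_times[chopped_sim_arg.roots[0]])
        v_rigid = rigid.locate(sample, 1.0, 0.5 * cut, dispersal=1.0).V
        v_relaxed = relaxed.locate(sample, 1.0, 0.5 * cut, dispersal=1.0).V
        assert v_relaxed > v_rigid


def test_singular_root_matrix_diagnostic(loop_arg):
    basis = enumerate_minimal_paths(loop_arg)
    sp = np.zeros((3, 3))  # no informative time at all
    with pytest.raises(np.linalg.LinAlgError, match="singular"):
        mle_root_locations(np.array([0.0, 1.0]), basis, sp)
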