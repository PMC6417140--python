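"""Variational inference: gradient correctness, ELBO bound, phi updates and
parameter recovery on self-simulated data."""

import numpy as np
import pytest
from scipy import stats

import dosealign.inference as inf
from dosealign import (
    CloneAssignModel,
    CloneProfile,
    ModelHyperparams,
    SimulationConfig,
    assignment_accuracy,
    simulate_dataset,
)
from dosealign.inference import (
    _model_arrays,
    _params_from_state,
    _pass,
    _softmax_rows,
    elbo,
    initialize_state,
    update_phi,
)


def _small_model(seed=3, n=12, g=10, c=2, **kw):
    config = SimulationConfig(n_cells=n, n_genes=g, n_clones=c, seed=seed,
                              segment_size=3, **kw)
    sim = simulate_dataset(config, seed=seed)
    return sim, CloneAssignModel(sim.expression, sim.clone_profile,
                                 n_residual_factors=2, n_rbf_bases=5)


class TestInitialization:
    def test_deterministic_given_seed(self, tiny_expression, tiny_profile,
                                      default_hyper, no_covariates):
        s1 = initialize_state(tiny_expression.counts, tiny_profile,
                              no_covariates, default_hyper, seed=7)
        s2 = initialize_state(tiny_expression.counts, tiny_profile,
                              no_covariates, default_hyper, seed=7)
        np.testing.assert_array_equal(s1.psi, s2.psi)
        np.testing.assert_array_equal(s1.W, s2.W)
        np.testing.assert_array_equal(s1.nu, s2.nu)

    def test_phi_uniform_and_anchor(self, tiny_expression, tiny_profile,
                                    default_hyper, no_covariates):
        s = initialize_state(tiny_expression.counts, tiny_profile,
                             no_covariates, default_hyper, seed=0)
        np.testing.assert_allclose(s.phi, 0.5)
        assert s.nu[0] == 0.0 and s.rho[0] == 0.0
        np.testing.assert_array_equal(s.s, tiny_expression.counts.sum(axis=1))

    def test_zero_count_cell_rejected(self, tiny_profile, default_hyper,
                                      no_covariates):
        counts = np.ones((5, 8), dtype=int)
        counts[2] = 0
        with pytest.raises(ValueError, match="zero total counts"):
            initialize_state(counts, tiny_profile, no_covariates,
                             default_hyper, seed=0)


class TestGradients:
    @pytest.mark.parametrize("fused", [True, False])
    def test_analytic_gradients_match_finite_differences(self, fused,
                                                         monkeypatch):
        monkeypatch.setattr(inf, "USE_FUSED_KERNEL",
                            fused and inf._kernels.HAVE_NUMBA)
        sim, model = _small_model(seed=5, n=8, g=9)
        hyper = model.hyper
        Y, F, X = _model_arrays(model.expression.counts, model.clone_profile,
                                model.covariates, hyper)
        state = initialize_state(Y, model.clone_profile, model.covariates,
                                 hyper, seed=1)
        params = _params_from_state(state, hyper)
        rng = np.random.default_rng(2)
        eps = rng.standard_normal((1, Y.shape[1]))
        eps[:, 0] = 0.0
        phi = rng.dirichlet(np.ones(2), size=Y.shape[0])
        chi = np.array([0.8, 1.4])
        args = (Y, F, X, params, phi, chi, state.rbf_centers,
                state.rbf_bandwidth, hyper, eps)
        _, _, grads = _pass(*args)

        def value(p):
            v, _, _ = _pass(Y, F, X, p, phi, chi, state.rbf_centers,
                            state.rbf_bandwidth, hyper, eps)
            return v

        h = 1e-6
        rng_idx = np.random.default_rng(0)
        for key in ("nu", "rho_u", "psi", "W", "alpha"):
            arr = params[key]
            for idx in rng_idx.choice(arr.size, size=min(4, arr.size),
                                      replace=False):
                p2 = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                      for k, v in params.items()}
                p2[key].flat[idx] += h
                up = value(p2)
                p2[key].flat[idx] -= 2 * h
                down = value(p2)
                numeric = (up - down) / (2 * h)
                assert grads[key].flat[idx] == pytest.approx(
                    numeric, rel=5e-4, abs=1e-5
                ), f"{key}[{idx}]"

    def test_fused_kernel_matches_numpy_path(self):
        if not inf._kernels.HAVE_NUMBA:
            pytest.skip("numba unavailable")
        sim, model = _small_model(seed=9, n=10, g=8, c=3)
        hyper = model.hyper
        Y, F, X = _model_arrays(model.expression.counts, model.clone_profile,
                                model.covariates, hyper)
        state = initialize_state(Y, model.clone_profile, model.covariates,
                                 hyper, seed=4)
        params = _params_from_state(state, hyper)
        rng = np.random.default_rng(4)
        eps = rng.standard_normal((2, Y.shape[1]))
        eps[:, 0] = 0.0
        phi = rng.dirichlet(np.ones(3), size=Y.shape[0])
        chi = np.ones(2)
        args = (Y, F, X, params, phi, chi, state.rbf_centers,
                state.rbf_bandwidth, hyper, eps)
        old = inf.USE_FUSED_KERNEL
        try:
            inf.USE_FUSED_KERNEL = True
            v1, l1, g1 = _pass(*args)
            inf.USE_FUSED_KERNEL = False
            v2, l2, g2 = _pass(*args)
        finally:
            inf.USE_FUSED_KERNEL = old
        assert v1 == pytest.approx(v2, rel=1e-12)
        np.testing.assert_allclose(l1, l2, rtol=1e-10)
        for k in g1:
            np.testing.assert_allclose(g1[k], g2[k], rtol=1e-6, atol=1e-9)


class TestElbo:
    def test_elbo_bounded_by_quadrature_evidence(self):
        """With one free per-copy expression parameter the model evidence is
        a 1-D integral; the ELBO must lower-bound it."""
        rng = np.random.default_rng(0)
        counts = rng.poisson([[4, 6], [8, 3]])
        profile = CloneProfile(
            copy_number=np.array([[2, 2], [2, 4]]),
            clone_labels=np.array(["A", "B"], dtype=object),
            gene_ids=np.array(["g0", "g1"], dtype=object),
        )
        hyper = ModelHyperparams(n_residual_factors=1, n_rbf_bases=3)
        state = initialize_state(counts, profile, None, hyper, seed=0)
        # freeze nuisance point parameters at exactly zero so likelihood
        # depends only on mu_2
        state.psi[:] = 0.0
        state.W[:] = 0.0
        n, c = 2, 2

        from dosealign.model import nb_log_likelihood, rbf_dispersion, dosage_function

        def loglik_given_mu2(mu2):
            mu = np.array([1.0, mu2])
            total = np.zeros((n, c))
            f = dosage_function(profile.copy_number, hyper.zeta)
            for ci in range(c):
                w = mu * f[:, ci]
                m = state.s[:, None] * w / w.sum()
                r = rbf_dispersion(m, state.a, state.rbf_centers,
                                   state.rbf_bandwidth)
                total[:, ci] = nb_log_likelihood(counts, m, r).sum(axis=1)
            return total

        grid = np.linspace(-6, 6, 4001)
        log_prior = stats.norm.logpdf(grid)
        per_cell = np.zeros((len(grid), n))
        for gi, lg in enumerate(grid):
            lnc = loglik_given_mu2(np.exp(lg))
            per_cell[gi] = np.log(np.exp(lnc).mean(axis=1))  # uniform z prior
        integrand = log_prior + per_cell.sum(axis=1)
        from scipy.special import logsumexp

        log_evidence = logsumexp(integrand) + np.log(grid[1] - grid[0])
        # point-parameter priors enter both sides identically
        log2pi = np.log(2 * np.pi)
        prior_const = (
            -0.5 * (state.psi**2).sum() - 0.5 * log2pi * state.psi.size
            + (0.5 * np.log(state.chi) * state.W.shape[0]).sum()
            - 0.5 * log2pi * state.W.size
            + (np.log(state.chi) - state.chi).sum()
            - stats.gamma.logpdf(1.0, a=2) * 0  # gammaln(2)=0
        )
        draws = np.random.default_rng(1).standard_normal((3000, 2))
        draws[:, 0] = 0.0
        est = elbo(counts, profile, None, state, hyper, draws)
        assert est.value <= log_evidence + prior_const + 0.05

    def test_degenerate_q_mu_is_draw_independent(self):
        sim, model = _small_model(seed=6)
        hyper = model.hyper
        state = initialize_state(model.expression.counts, model.clone_profile,
                                 model.covariates, hyper, seed=0)
        state.rho[:] = 1e-9
        state.rho[0] = 0.0
        e1 = elbo(model.expression.counts, model.clone_profile,
                  model.covariates, state, hyper,
                  np.random.default_rng(1).standard_normal((1, 10)))
        e2 = elbo(model.expression.counts, model.clone_profile,
                  model.covariates, state, hyper,
                  np.random.default_rng(2).standard_normal((1, 10)))
        # rho is floored at 1e-6 when packing, so allow that much leakage
        assert e1.value == pytest.approx(e2.value, abs=0.02)


class TestUpdatePhi:
    def test_rows_sum_to_one(self):
        sim, model = _small_model(seed=8)
        hyper = model.hyper
        state = initialize_state(model.expression.counts, model.clone_profile,
                                 model.covariates, hyper, seed=0)
        phi = update_phi(model.expression.counts, model.clone_profile,
                         model.covariates, state, hyper,
                         np.zeros((1, model.expression.n_genes)))
        np.testing.assert_allclose(phi.sum(axis=1), 1.0, atol=1e-12)
        assert (phi >= 0).all()

    def test_duplicate_clone_columns_get_equal_probability(self):
        """Clones with identical copy-number profiles are indistinguishable,
        so their assignment probabilities must be exactly equal."""
        sim, _ = _small_model(seed=10, n=10, g=9, c=2)
        lam = sim.clone_profile.copy_number
        profile3 = CloneProfile(
            copy_number=np.column_stack([lam[:, 0], lam[:, 0], lam[:, 1]]),
            clone_labels=np.array(["A1", "A2", "B"], dtype=object),
            gene_ids=sim.clone_profile.gene_ids,
        )
        model = CloneAssignModel(sim.expression, profile3,
                                 n_residual_factors=1, n_rbf_bases=5)
        hyper = model.hyper
        state = initialize_state(model.expression.counts, model.clone_profile,
                                 model.covariates, hyper, seed=0)
        phi = update_phi(model.expression.counts, model.clone_profile,
                         model.covariates, state, hyper,
                         np.zeros((1, model.expression.n_genes)))
        np.testing.assert_allclose(phi[:, 0], phi[:, 1], rtol=1e-10)

    def test_cell_matching_one_clone_is_confidently_assigned(self):
        """A deep cell whose counts equal one clone's expected profile should
        be assigned there with near certainty."""
        from dosealign.model import expected_counts

        sim, model = _small_model(seed=12, n=6, g=12)
        hyper = model.hyper
        state = initialize_state(model.expression.counts, model.clone_profile,
                                 model.covariates, hyper, seed=0)
        state.psi[:] = 0.0
        state.W[:] = 0.0
        state.s[:] = 1e4
        # dispersion curve must cover the rescaled count range
        state.rbf_centers = np.linspace(0.0, 4000.0, len(state.a))
        delta = state.rbf_centers[1] - state.rbf_centers[0]
        state.rbf_bandwidth = 1.0 / (2 * delta**2)
        mean0 = expected_counts(state, 0, model.clone_profile, hyper=hyper)
        counts = np.round(mean0).astype(int)
        phi = update_phi(counts, model.clone_profile, model.covariates,
                         state, hyper, np.zeros((1, 12)))
        assert (phi[:, 0] > 0.99).all()

    def test_gene_permutation_equivariance(self):
        """With deterministic noise, permuting gene order (anchor kept first)
        leaves the assignment probabilities unchanged."""
        sim, model = _small_model(seed=13, n=10, g=9)
        hyper = model.hyper
        state = initialize_state(model.expression.counts, model.clone_profile,
                                 model.covariates, hyper, seed=0)
        zero = np.zeros((1, 9))
        phi = update_phi(model.expression.counts, model.clone_profile,
                         model.covariates, state, hyper, zero)
        perm = np.concatenate([[0], 1 + np.random.default_rng(0).permutation(8)])
        expr_p = sim.expression.subset_genes(perm)
        prof_p = model.clone_profile.subset_genes(perm)
        state_p = initialize_state(expr_p.counts, prof_p, model.covariates,
                                   hyper, seed=0)
        for field in ("nu", "rho", "W"):
            setattr(state_p, field, getattr(state, field)[perm])
        state_p.psi = state.psi
        state_p.a = state.a
        phi_p = update_phi(expr_p.counts, prof_p, model.covariates, state_p,
                           hyper, zero)
        np.testing.assert_allclose(phi, phi_p, rtol=1e-8)

    def test_all_nonfinite_likelihood_names_cell(self):
        L = np.array([[0.0, 1.0], [-np.inf, -np.inf]])
        with pytest.raises(FloatingPointError, match="cell_b"):
            _softmax_rows(L, cell_ids=np.array(["cell_a", "cell_b"]))


class TestFit:
    def test_recovers_simulated_assignments(self):
        config = SimulationConfig(n_cells=200, n_genes=100, n_clones=2,
                                  seed=21, dosage_proportion=1.0)
        sim = simulate_dataset(config, seed=21)
        model = CloneAssignModel(sim.expression, sim.clone_profile,
                                 max_iterations=250)
        res = model.fit(seed=1)
        acc = assignment_accuracy(res.state.phi, sim.true_clone_index)
        assert acc >= 0.95

    def test_reproducible_given_seed(self):
        sim, _ = _small_model(seed=30, n=15, g=12)
        kw = dict(n_residual_factors=1, n_rbf_bases=5, max_iterations=40)
        r1 = CloneAssignModel(sim.expression, sim.clone_profile, **kw).fit(seed=3)
        r2 = CloneAssignModel(sim.expression, sim.clone_profile, **kw).fit(seed=3)
        np.testing.assert_array_equal(r1.state.phi, r2.state.phi)
        np.testing.assert_array_equal(r1.elbo_trace, r2.elbo_trace)

    def test_elbo_ascends_on_average(self):
        sim, model = _small_model(seed=31, n=40, g=20)
        res = CloneAssignModel(sim.expression, sim.clone_profile,
                               n_residual_factors=1, n_rbf_bases=5,
                               max_iterations=150).fit(seed=2)
        trace = res.elbo_trace
        assert np.mean(trace[-50:]) >= trace[0]

    def test_anchor_held_throughout(self):
        sim, model = _small_model(seed=32)
        res = CloneAssignModel(sim.expression, sim.clone_profile,
                               n_residual_factors=1, n_rbf_bases=5,
                               max_iterations=30).fit(seed=2)
        assert res.state.nu[0] == 0.0
        assert res.state.rho[0] == 0.0

    def test_nonconvergence_is_flag_not_error(self):
        sim, model = _small_model(seed=33)
        res = CloneAssignModel(sim.expression, sim.clone_profile,
                               n_residual_factors=1, n_rbf_bases=5,
                               max_iterations=5).fit(seed=2)
        assert res.converged is False
        assert res.n_iterations == 5

    def test_size_factor_inference_mode_runs(self):
        sim, model = _small_model(seed=34, n=15, g=12)
        res = CloneAssignModel(sim.expression, sim.clone_profile,
                               n_residual_factors=1, n_rbf_bases=5,
                               size_factor_mode="inferred",
                               max_iterations=40).fit(seed=2)
        assert (res.state.s > 0).all()
        # inferred sizes move away from the raw totals
        assert not np.array_equal(res.state.s,
                                  sim.expression.counts.sum(axis=1))

    def test_results_surface(self):
        sim, model = _small_model(seed=35, n=15, g=12)
        res = CloneAssignModel(sim.expression, sim.clone_profile,
                               n_residual_factors=1, n_rbf_bases=5,
                               max_iterations=25).fit(seed=2)
        probs = res.assignment_probabilities
        assert probs.shape == (15, 2)
        assert (res.map_clone == np.array(probs.columns)[
            np.argmax(probs.to_numpy(), axis=1)]).all()
        text = res.summary()
        assert "clones: 2" in text and "MAP clone prevalence" in text
        assert res.clone_prevalence().sum() == pytest.approx(1.0)
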