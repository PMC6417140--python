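"""Mean-field variational inference for the dosage model.

The variational family factorizes as ``q(z, mu) = prod_n q(z_n) prod_g
q(mu_g)`` with categorical ``q(z_n = c) = phi_nc`` and log-normal ``q(mu_g)``
reparameterized as ``mu_g = exp(nu_g + rho_g * eps)``, ``eps ~ N(0,1)``. All
remaining parameters (psi, W, B, a, optionally log s) are optimized as points.

The expectation over ``q(z)`` is taken analytically; the expectation over
``q(mu)`` is a Monte-Carlo estimate (S draws, default 1) differentiated with
the reparameterization trick. Gradients of the ELBO with respect to every
unconstrained parameter are derived analytically: writing
``u_ngc = mu_g f(lambda_gc) exp(x_n.B_g + psi_n.w_g)`` and
``m_ngc = s_n u_ngc / sum_g' u_ng'c``, a perturbation ``d log u_ngc`` moves
all means of that (cell, clone) through the normalization,

    d m_ng'c / d log u_ngc = m_ng'c (1[g = g'] - m_ngc / s_n),

which reduces every per-gene gradient to one weighted residual matrix
``H_ng = sum_c phi_nc (dl/dm * m)_ngc - (m/s) * rowsum`` that is then
contracted against the design (1 for nu, eps for rho, X for B, W/psi for the
factor terms). The inverse-dispersion ``r = phi(m)`` built from RBF kernels
contributes both directly (dl/dr, giving the amplitude gradients) and through
``dr/dm``. Ascent uses Adam; ``phi`` and the factor precisions ``chi`` are
updated by their closed-form coordinate optima each iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from . import _kernels
from .model import (
    DISPERSION_FLOOR,
    CloneAssignModel,
    ModelHyperparams,
    VariationalState,
    dosage_function,
    rbf_centers,
)
from .results import CloneAssignResults

# fused numba kernel for the per-clone likelihood block; the numpy fallback
# below is mathematically identical (tested for equivalence)
USE_FUSED_KERNEL = _kernels.HAVE_NUMBA

logger = logging.getLogger("dosealign")

__all__ = ["ELBOEstimate", "initialize_state", "elbo", "update_phi", "fit", "Adam"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ELBOEstimate:
    value: float
    iteration: int
    mc_sample_count: int


def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(y):
    # inverse of log(1 + e^x); y must be > 0
    return np.where(y > 30, y, np.log(np.expm1(np.maximum(y, 1e-12))))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class Adam:
    """Adam optimizer over a dict of named parameter arrays (maximization)."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            params[k] += self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


# ---------------------------------------------------------------------------
# parameter packing: unconstrained <-> VariationalState
# ---------------------------------------------------------------------------

def _state_from_params(params, phi, chi, centers, b, hyper, elbo_trace=None):
    rho = _softplus(params["rho_u"]).copy()
    rho[0] = 0.0
    nu = params["nu"].copy()
    nu[0] = 0.0
    if "log_s" in params:
        s = np.exp(params["log_s"])
    else:
        s = params["s_fixed"]
    return VariationalState(
        phi=phi.copy(),
        nu=nu,
        rho=rho,
        psi=params["psi"].copy(),
        W=params["W"].copy(),
        chi=chi.copy(),
        B=params["B"].copy(),
        a=_softplus(params["alpha"]),
        s=s.copy(),
        rbf_centers=centers.copy(),
        rbf_bandwidth=b,
        elbo_trace=list(elbo_trace) if elbo_trace is not None else [],
    )


def _params_from_state(state: VariationalState, hyper: ModelHyperparams) -> dict:
    params = {
        "nu": state.nu.copy(),
        "rho_u": np.asarray(_inv_softplus(np.maximum(state.rho, 1e-6))),
        "psi": state.psi.copy(),
        "W": state.W.copy(),
        "B": state.B.copy(),
        "alpha": np.asarray(_inv_softplus(np.maximum(state.a, 1e-6))),
    }
    if hyper.size_factor_mode == "inferred":
        params["log_s"] = np.log(state.s)
    else:
        params["s_fixed"] = state.s.copy()
    return params


def initialize_state(
    counts: np.ndarray,
    clone_profile,
    covariates,
    hyper: ModelHyperparams,
    seed: int | None = None,
) -> VariationalState:
    """Deterministic-given-seed starting point.

    phi is uniform over clones; ``nu_g`` starts at the log mean expression of
    gene g relative to gene 1 (the anchor, held at 0 throughout); ``rho``
    starts small (0.1); factor/covariate parameters start as 0.01-scaled
    Gaussian noise; RBF amplitudes start at 1; size factors are the per-cell
    total counts.
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(counts, dtype=np.float64)
    n, g = Y.shape
    c = clone_profile.n_clones
    p = covariates.n_covariates if covariates is not None else 0
    q = hyper.n_residual_factors

    totals = Y.sum(axis=1)
    if (totals <= 0).any():
        bad = np.where(totals <= 0)[0][:5]
        raise ValueError(f"cells with zero total counts (rows {bad.tolist()})")

    mean_g = Y.mean(axis=0)
    nu = np.log((mean_g + 1e-3) / (mean_g[0] + 1e-3))
    nu[0] = 0.0
    rho = np.full(g, 0.1)
    rho[0] = 0.0
    centers, b = rbf_centers(Y, hyper.n_rbf_bases)
    state = VariationalState(
        phi=np.full((n, c), 1.0 / c),
        nu=nu,
        rho=rho,
        psi=0.01 * rng.standard_normal((n, q)),
        W=0.01 * rng.standard_normal((g, q)),
        chi=np.ones(q),
        B=0.01 * rng.standard_normal((g, p)),
        a=np.ones(hyper.n_rbf_bases),
        s=totals.astype(np.float64),
        rbf_centers=centers,
        rbf_bandwidth=b,
    )
    state.validate()
    return state


# ---------------------------------------------------------------------------
# forward/backward pass
# ---------------------------------------------------------------------------

def _pass(Y, F, X, params, phi, chi, centers, b, hyper, eps_draws,
          allele_log_lik=None, want_grads=True):
    """One MC forward (and optionally backward) sweep.

    Returns (elbo_value, L, grads) where L is the S-averaged N×C matrix of
    E_q(mu)[log p(y_n | z_n = c)] and grads maps unconstrained parameter
    names to ELBO gradients.
    """
    n, g = Y.shape
    c_clones = F.shape[1]
    S = eps_draws.shape[0]

    nu = params["nu"].copy()
    nu[0] = 0.0
    rho_u = params["rho_u"]
    rho = _softplus(rho_u)
    rho = rho.copy()
    rho[0] = 0.0
    psi, W, B = params["psi"], params["W"], params["B"]
    alpha = params["alpha"]
    a = _softplus(alpha)
    if "log_s" in params:
        s = np.exp(params["log_s"])
    else:
        s = params["s_fixed"]

    logbase = psi @ W.T
    if X is not None and X.size:
        logbase = logbase + X @ B.T
    logbase = np.clip(logbase, -50.0, 50.0)
    base = np.exp(logbase)

    nz = np.flatnonzero(Y)  # counts are identical across clones/draws
    y_nz = Y.flat[nz].astype(np.float64)
    gln_y1 = gammaln(y_nz + 1.0)

    L = np.zeros((n, c_clones))
    H = np.zeros((n, g)) if want_grads else None
    grad_a = np.zeros(a.shape[0]) if want_grads else None
    grad_nu_like = np.zeros(g) if want_grads else None
    grad_rho_like = np.zeros(g) if want_grads else None
    grad_log_s = np.zeros(n) if want_grads else None
    ac = a * centers

    for si in range(S):
        eps = eps_draws[si]
        mu = np.exp(nu + rho * eps)
        mu[0] = 1.0
        H_s = np.zeros((n, g)) if want_grads else None
        for c in range(c_clones):
            A = base * (mu * F[:, c])
            D = A.sum(axis=1, keepdims=True)
            m = np.maximum(s[:, None] * A / D, 1e-12)
            if USE_FUSED_KERNEL:
                L_col, H_add, ga, gls = _kernels.clone_block(
                    Y, m, s, np.ascontiguousarray(phi[:, c]), a, centers,
                    float(b), DISPERSION_FLOOR, want_grads,
                )
                L[:, c] += L_col / S
                if want_grads:
                    H_s += H_add
                    grad_a += ga / S
                    grad_log_s += gls / S
                continue
            K = np.exp(-b * (m[:, :, None] - centers) ** 2)
            r_raw = K @ a
            floored = r_raw < DISPERSION_FLOOR
            r = np.maximum(r_raw, DISPERSION_FLOOR)
            rm = r + m
            log_r = np.log(r)
            log_rm = np.log(rm)
            ll = r * (log_r - log_rm)
            rf = r.flat[nz]
            mf = m.flat[nz]
            rmf = rm.flat[nz]
            ll.flat[nz] += (
                gammaln(y_nz + rf) - gammaln(rf) - gln_y1
                + y_nz * (np.log(mf) - log_rm.flat[nz])
            )
            L[:, c] += ll.sum(axis=1) / S
            if not want_grads:
                continue
            dldm = -r / rm
            dldm.flat[nz] += y_nz / mf - y_nz / rmf
            dldr = (log_r - log_rm) + m / rm
            dldr.flat[nz] += digamma(y_nz + rf) - digamma(rf) - y_nz / rmf
            dldr[floored] = 0.0
            drdm = -2.0 * b * (r_raw * m - K @ ac)
            gm = dldm + dldr * drdm
            pw = phi[:, c][:, None]
            Gm = pw * gm * m
            Sn = Gm.sum(axis=1)
            H_s += Gm - (m / s[:, None]) * Sn[:, None]
            grad_a += phi[:, c] @ np.einsum("ng,ngm->nm", dldr, K) / S
            grad_log_s += Sn / S
        if want_grads:
            H += H_s / S
            col = H_s.sum(axis=0)
            grad_nu_like += col / S
            grad_rho_like += col * eps / S

    # analytic terms (independent of the MC draw)
    rho_free = rho[1:]
    kl_mu = float(np.sum(0.5 * (rho_free**2 + nu[1:] ** 2 - 1.0) - np.log(rho_free)))
    prior_psi = float(np.sum(-0.5 * psi**2 - 0.5 * _LOG2PI))
    prior_w = float(np.sum(0.5 * np.log(chi) - 0.5 * chi * W**2 - 0.5 * _LOG2PI))
    prior_chi = float(np.sum(np.log(chi) - chi - gammaln(2.0)))

    Ltot = L if allele_log_lik is None else L + allele_log_lik
    phi_safe = np.maximum(phi, 1e-300)
    entropy_z = float(-(phi * np.log(phi_safe)).sum())
    z_prior = -n * np.log(c_clones)
    elbo_val = (
        float((phi * Ltot).sum())
        + entropy_z + z_prior + prior_psi + prior_w + prior_chi - kl_mu
    )
    if not np.isfinite(elbo_val):
        for name, term in (
            ("likelihood", float((phi * Ltot).sum())),
            ("entropy_z", entropy_z),
            ("prior_psi", prior_psi),
            ("prior_w", prior_w),
            ("prior_chi", prior_chi),
            ("kl_mu", -kl_mu),
        ):
            if not np.isfinite(term):
                raise FloatingPointError(f"ELBO term '{name}' is non-finite")

    grads = None
    if want_grads:
        grad_nu = grad_nu_like - nu
        grad_nu[0] = 0.0
        grad_rho = grad_rho_like - (rho - 1.0 / np.maximum(rho, 1e-12))
        grad_rho_u = grad_rho * _sigmoid(rho_u)
        grad_rho_u[0] = 0.0
        grads = {
            "nu": grad_nu,
            "rho_u": grad_rho_u,
            "psi": H @ W - psi,
            "W": H.T @ psi - chi * W,
            "alpha": grad_a * _sigmoid(alpha),
        }
        if X is not None and X.size:
            grads["B"] = H.T @ X
        else:
            grads["B"] = np.zeros_like(B)
        if "log_s" in params:
            grads["log_s"] = grad_log_s
    return elbo_val, Ltot, grads


def _model_arrays(counts, clone_profile, covariates, hyper):
    Y = np.asarray(counts, dtype=np.float64)
    F = dosage_function(clone_profile.copy_number, hyper.zeta)
    X = covariates.X if (covariates is not None and covariates.n_covariates) else None
    return Y, F, X


def elbo(counts, clone_profile, covariates, state: VariationalState,
         hyper: ModelHyperparams, noise_draw: np.ndarray,
         allele_log_lik=None) -> ELBOEstimate:
    """Monte-Carlo ELBO estimate at a given state using supplied S×G standard
    normal draws; the expectation over clone assignments is analytic."""
    noise_draw = np.atleast_2d(np.asarray(noise_draw, dtype=np.float64))
    Y, F, X = _model_arrays(counts, clone_profile, covariates, hyper)
    params = _params_from_state(state, hyper)
    val, _, _ = _pass(Y, F, X, params, state.phi, state.chi,
                      state.rbf_centers, state.rbf_bandwidth, hyper,
                      noise_draw, allele_log_lik=allele_log_lik,
                      want_grads=False)
    return ELBOEstimate(value=val, iteration=len(state.elbo_trace),
                        mc_sample_count=noise_draw.shape[0])


def update_phi(counts, clone_profile, covariates, state: VariationalState,
               hyper: ModelHyperparams, noise_draw: np.ndarray,
               allele_log_lik=None, cell_ids=None) -> np.ndarray:
    """Closed-form coordinate update of the clone-assignment probabilities:
    ``phi_nc ∝ exp(E_q[log p(y_n | z_n = c)])``, row-normalized."""
    noise_draw = np.atleast_2d(np.asarray(noise_draw, dtype=np.float64))
    Y, F, X = _model_arrays(counts, clone_profile, covariates, hyper)
    params = _params_from_state(state, hyper)
    _, Ltot, _ = _pass(Y, F, X, params, state.phi, state.chi,
                       state.rbf_centers, state.rbf_bandwidth, hyper,
                       noise_draw, allele_log_lik=allele_log_lik,
                       want_grads=False)
    return _softmax_rows(Ltot, cell_ids)


def _softmax_rows(L, cell_ids=None):
    bad = ~np.isfinite(L.max(axis=1))
    if bad.any():
        idx = np.where(bad)[0]
        names = (np.asarray(cell_ids)[idx][:5].tolist()
                 if cell_ids is not None else idx[:5].tolist())
        raise FloatingPointError(
            f"all clone log-likelihoods non-finite for cell(s) {names}"
        )
    Lc = L - L.max(axis=1, keepdims=True)
    e = np.exp(Lc)
    return e / e.sum(axis=1, keepdims=True)


def fit(model: CloneAssignModel, seed: int | None = None,
        verbose: bool = False) -> CloneAssignResults:
    """Adam ascent on the ELBO with closed-form phi and chi updates.

    Each iteration draws S fresh standard-normal vectors for mu, takes one
    Adam step on all unconstrained parameters, then sets phi to its exact
    coordinate optimum and chi to its conditional maximizer
    ``chi_k = (G/2 + 1) / (sum_g w_gk^2 / 2 + 1)``. Convergence is declared
    when the window-10 smoothed ELBO changes by less than
    ``convergence_rel_elbo`` percent.
    """
    hyper = model.hyper
    counts = model.expression.counts
    Y, F, X = _model_arrays(counts, model.clone_profile, model.covariates, hyper)
    n, g = Y.shape

    rng = np.random.default_rng(seed)
    state = initialize_state(counts, model.clone_profile, model.covariates,
                             hyper, seed=seed)
    params = _params_from_state(state, hyper)
    chi = state.chi.copy()
    phi = state.phi.copy()
    centers, b = state.rbf_centers, state.rbf_bandwidth
    allele = model._allele_log_lik

    opt_keys = [k for k in params if k != "s_fixed"]
    opt = Adam({k: params[k] for k in opt_keys}, lr=hyper.learning_rate)

    trace: list[float] = []
    converged = False
    window = 10
    threshold = hyper.convergence_rel_elbo / 100.0
    it = 0
    for it in range(1, hyper.max_iterations + 1):
        eps = rng.standard_normal((hyper.mc_samples, g))
        eps[:, 0] = 0.0
        val, Ltot, grads = _pass(Y, F, X, params, phi, chi, centers, b,
                                 hyper, eps, allele_log_lik=allele)
        trace.append(val)
        opt.step(params, {k: grads[k] for k in opt_keys})
        params["nu"][0] = 0.0
        phi = _softmax_rows(Ltot, model.expression.cell_ids)
        chi = (g / 2.0 + 1.0) / (0.5 * (params["W"] ** 2).sum(axis=0) + 1.0)
        if verbose and (it == 1 or it % 50 == 0):
            logger.info("iter %d  elbo %.4f", it, val)
        if it >= 2 * window:
            sm_new = float(np.mean(trace[-window:]))
            sm_old = float(np.mean(trace[-2 * window:-window]))
            if abs(sm_new - sm_old) < threshold * abs(sm_old):
                converged = True
                break

    if not converged:
        logger.warning(
            "fit did not reach the %g%% smoothed-ELBO convergence threshold "
            "in %d iterations", hyper.convergence_rel_elbo, it,
        )
    final_state = _state_from_params(params, phi, chi, centers, b, hyper,
                                     elbo_trace=trace)
    final_state.validate()
    return CloneAssignResults(
        model=model,
        state=final_state,
        converged=converged,
        n_iterations=it,
    )
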