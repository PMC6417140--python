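"""The copy-number dosage model of clone-specific gene expression.

A cell's expression profile is linked to its (latent) clone of origin through
the clone's copy-number profile: conditional on cell ``n`` belonging to clone
``c``, the expected count of gene ``g`` is

    E[y_ng | z_n = c] = s_n * mu_g f(lambda_gc) exp(x_n.B_g + psi_n.w_g)
                        / sum_g' mu_g' f(lambda_g'c) exp(x_n.B_g' + psi_n.w_g')

where ``s_n`` is the cell's read depth, ``mu_g`` the per-copy expression of
gene ``g`` relative to gene 1 (``mu_1 = 1`` anchors the scale), ``f`` the
capped dosage function ``f(lambda) = min(lambda, zeta)``, ``x_n.B_g`` known
covariate effects and ``psi_n.w_g`` a low-rank structured-noise term. The
denominator makes expression *relative*: amplifying one highly expressed gene
depresses the expected counts of every other gene in that clone.

Counts follow a negative binomial whose inverse-dispersion is a non-parametric
function of the mean built from radial basis function kernels,
``phi(mu) = sum_i a_i exp(-b (mu - c_i)^2)``, with variance
``Var[y] = m (1 + m / phi(m))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .data import (
    AlleleData,
    CloneProfile,
    Covariates,
    ExpressionCounts,
    harmonize,
)

__all__ = [
    "ModelHyperparams",
    "VariationalState",
    "dosage_function",
    "rbf_centers",
    "rbf_dispersion",
    "nb_log_likelihood",
    "expected_counts",
    "log_joint",
    "CloneAssignModel",
]

# Floor for f(0): a fully deleted gene keeps a tiny positive expected
# expression so the likelihood stays finite.
DOSAGE_FLOOR = 1e-6
# Floor for the RBF inverse-dispersion, keeping the NB mass defined.
DISPERSION_FLOOR = 1e-3


@dataclass
class ModelHyperparams:
    """Tunable model and optimizer settings.

    Attributes
    ----------
    zeta
        Dosage cap: copy numbers at or above ``zeta`` contribute ``zeta``.
    n_residual_factors
        Number of structured-noise factors Q; forced to 1 when fewer than
        100 genes are modelled (set at model construction).
    n_rbf_bases
        Number M of RBF kernels for the mean-dispersion curve; centers are
        evenly spaced over the observed raw-count range and the bandwidth is
        ``b = 1 / (2 delta^2)`` with ``delta`` the center spacing.
    mc_samples
        Monte-Carlo samples S per ELBO/gradient evaluation.
    convergence_rel_elbo
        Relative change (in percent) of the window-10 smoothed ELBO below
        which the fit is declared converged.
    size_factor_mode
        "fixed": s_n is the cell's total count over retained genes.
        "inferred": log s_n is optimized jointly with the other parameters.
    """

    zeta: int = 6
    n_residual_factors: int = 6
    n_rbf_bases: int = 20
    mc_samples: int = 1
    convergence_rel_elbo: float = 1e-6  # percent
    learning_rate: float = 0.05
    max_iterations: int = 500
    random_seed: int | None = None
    size_factor_mode: str = "fixed"

    def __post_init__(self):
        if self.zeta < 1:
            raise ValueError("zeta must be >= 1")
        if self.n_residual_factors < 1:
            raise ValueError("n_residual_factors must be >= 1")
        if self.n_rbf_bases < 1:
            raise ValueError("n_rbf_bases must be >= 1")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.size_factor_mode not in ("fixed", "inferred"):
            raise ValueError("size_factor_mode must be 'fixed' or 'inferred'")


@dataclass
class VariationalState:
    """All variational and point parameters of a (partially) fitted model.

    ``q(z_n = c) = phi[n, c]`` and ``q(mu_g)`` is the log-normal given by the
    transform ``mu_g = exp(nu_g + rho_g * eps)`` of standard normal noise;
    gene 1 is the scale anchor with ``mu_1 = 1`` (``nu[0] = rho[0] = 0``).
    Everything else (psi, W, chi, B, a, s) is point-optimized.
    """

    phi: np.ndarray
    nu: np.ndarray
    rho: np.ndarray
    psi: np.ndarray
    W: np.ndarray
    chi: np.ndarray
    B: np.ndarray
    a: np.ndarray
    s: np.ndarray
    rbf_centers: np.ndarray
    rbf_bandwidth: float
    elbo_trace: list = field(default_factory=list)

    def validate(self) -> None:
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("phi rows must sum to 1")
        if (self.phi < -1e-12).any() or (self.phi > 1 + 1e-12).any():
            raise ValueError("phi entries must lie in [0, 1]")
        if self.nu[0] != 0.0 or self.rho[0] != 0.0:
            raise ValueError("gene 1 anchor violated: require nu[0] = rho[0] = 0")
        if (self.s <= 0).any():
            raise ValueError("size factors must be positive")
        if (self.a < 0).any():
            raise ValueError("RBF amplitudes must be non-negative")


def dosage_function(lam, zeta: int = 6, floor: float = DOSAGE_FLOOR):
    """Capped copy-number dosage factor: ``min(lam, zeta)``, with a small
    positive floor at ``lam = 0`` (homozygous deletion) so means stay positive.
    """
    if zeta < 1:
        raise ValueError("zeta must be >= 1")
    lam_arr = np.asarray(lam, dtype=np.float64)
    if (lam_arr < 0).any():
        raise ValueError("copy numbers must be non-negative")
    out = np.where(lam_arr == 0, floor, np.minimum(lam_arr, float(zeta)))
    if np.isscalar(lam) or np.ndim(lam) == 0:
        return float(out)
    return out


def rbf_centers(counts: np.ndarray, n_bases: int) -> tuple[np.ndarray, float]:
    """Evenly spaced kernel centers over the observed raw-count range and the
    bandwidth ``b = 1/(2 delta^2)``; computed once before fitting."""
    lo, hi = float(np.min(counts)), float(np.max(counts))
    if hi <= lo:
        hi = lo + 1.0
    centers = np.linspace(lo, hi, n_bases)
    delta = (hi - lo) / max(n_bases - 1, 1)
    b = 1.0 / (2.0 * delta**2)
    return centers, b


def rbf_dispersion(mu, a: np.ndarray, centers: np.ndarray, b: float,
                   floor: float = DISPERSION_FLOOR):
    """Inverse-dispersion as a kernel-smooth function of the mean,
    ``phi(mu) = sum_i a_i exp(-b (mu - c_i)^2)``, floored at ``floor``."""
    mu_arr = np.asarray(mu, dtype=np.float64)
    k = np.exp(-b * (mu_arr[..., None] - centers) ** 2)
    out = np.maximum(k @ np.asarray(a, dtype=np.float64), floor)
    if np.isscalar(mu) or np.ndim(mu) == 0:
        return float(out)
    return out


def nb_log_likelihood(y, mean, phi_disp):
    """Negative-binomial log mass at counts ``y`` with mean ``m`` and
    inverse-dispersion ``r = phi_disp`` (variance ``m (1 + m/r)``)."""
    y_arr = np.asarray(y, dtype=np.float64)
    if (y_arr < 0).any():
        raise ValueError("counts must be non-negative")
    m = np.asarray(mean, dtype=np.float64)
    r = np.asarray(phi_disp, dtype=np.float64)
    if (m <= 0).any() or (r <= 0).any():
        raise ValueError("mean and dispersion must be positive")
    out = (
        gammaln(y_arr + r)
        - gammaln(r)
        - gammaln(y_arr + 1.0)
        + r * (np.log(r) - np.log(r + m))
        + y_arr * (np.log(m) - np.log(r + m))
    )
    if np.isscalar(y) and np.isscalar(mean) and np.isscalar(phi_disp):
        return float(out)
    return out


def _log_base(state: VariationalState, X: np.ndarray | None) -> np.ndarray:
    """N×G log of the covariate + structured-noise multiplier."""
    lb = state.psi @ state.W.T
    if X is not None and X.size:
        lb = lb + X @ state.B.T
    return np.clip(lb, -50.0, 50.0)


def expected_counts(
    state: VariationalState,
    clone_index: int,
    clone_profile: CloneProfile,
    covariates: Covariates | None = None,
    hyper: ModelHyperparams | None = None,
    mu: np.ndarray | None = None,
) -> np.ndarray:
    """N×G expected counts conditional on every cell belonging to one clone.

    Uses the plug-in ``mu = exp(nu)`` unless an explicit ``mu`` sample is
    given. Rows sum to ``s_n`` exactly by construction of the total-RNA
    normalization.
    """
    hyper = hyper or ModelHyperparams()
    if mu is None:
        mu = np.exp(state.nu)
    for name, arr in (("mu", mu), ("psi", state.psi), ("W", state.W),
                      ("B", state.B), ("s", state.s)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite values in parameter {name}")
    f = dosage_function(clone_profile.copy_number[:, clone_index], hyper.zeta)
    X = covariates.X if covariates is not None else None
    weights = np.exp(_log_base(state, X)) * (mu * f)  # N×G
    denom = weights.sum(axis=1, keepdims=True)
    return state.s[:, None] * weights / denom


def log_joint(
    counts: np.ndarray,
    clone_profile: CloneProfile,
    covariates: Covariates | None,
    state: VariationalState,
    hyper: ModelHyperparams,
    z: np.ndarray,
    mu: np.ndarray | None = None,
) -> float:
    """Log joint probability of counts and point parameters at a fixed clone
    assignment vector ``z`` (0-based clone indices), using ``mu = exp(nu)``
    unless a sample is supplied.

    Includes the NB likelihood and the Gaussian/Gamma priors on ``log mu``
    (genes 2..G), ``psi``, ``W`` and ``chi``; covariate coefficients carry no
    prior. Invariant to adding a constant to all ``log mu`` with the anchor
    re-applied, because the likelihood only sees normalized weights.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n, g = counts.shape
    z = np.asarray(z)
    if z.shape != (n,):
        raise ValueError(f"assignment vector z has shape {z.shape}, expected ({n},)")
    if mu is None:
        mu = np.exp(state.nu)
    if clone_profile.n_genes != g:
        raise ValueError(
            f"copy_number has {clone_profile.n_genes} genes but counts has {g}"
        )
    total = 0.0
    for c in np.unique(z):
        rows = np.where(z == c)[0]
        m_all = expected_counts(state, int(c), clone_profile, covariates, hyper, mu=mu)
        m = m_all[rows]
        r = rbf_dispersion(m, state.a, state.rbf_centers, state.rbf_bandwidth)
        total += float(nb_log_likelihood(counts[rows], m, r).sum())
    log2pi = np.log(2.0 * np.pi)
    log_mu = np.log(mu[1:])  # anchor gene excluded from the prior
    total += float(np.sum(-0.5 * log_mu**2 - 0.5 * log2pi))
    total += float(np.sum(-0.5 * state.psi**2 - 0.5 * log2pi))
    total += float(
        np.sum(0.5 * np.log(state.chi) - 0.5 * state.chi * state.W**2 - 0.5 * log2pi)
    )
    # chi_k ~ Gamma(shape=2, rate=1)
    total += float(np.sum(np.log(state.chi) - state.chi - gammaln(2.0)))
    return total


class CloneAssignModel:
    """Assigns scRNA-seq cells to scDNA-defined clones via copy-number dosage.

    Parameters
    ----------
    expression
        Raw counts (:class:`~dosealign.data.ExpressionCounts`).
    clone_profile
        Clone-specific copy numbers (:class:`~dosealign.data.CloneProfile`);
        gene sets are harmonized by exact id match, dropping (with a logged
        count) genes absent from either input.
    covariates
        Optional known per-cell covariates.
    allele_data
        Optional alt/ref counts at germline heterozygous SNVs with a
        variant-by-clone copy-number table; adds the allelic-imbalance
        likelihood to the assignment.
    **hyper_overrides
        Any :class:`ModelHyperparams` field.
    """

    def __init__(
        self,
        expression: ExpressionCounts,
        clone_profile: CloneProfile,
        covariates: Covariates | None = None,
        allele_data: AlleleData | None = None,
        **hyper_overrides,
    ):
        self.expression, self.clone_profile = harmonize(expression, clone_profile)
        if not (np.ptp(self.clone_profile.copy_number, axis=1) > 0).any():
            raise ValueError(
                "no gene with inter-clone copy-number difference after "
                "harmonization: assignment is unidentifiable"
            )
        hyper = ModelHyperparams(**hyper_overrides)
        if self.expression.n_genes < 100 and "n_residual_factors" not in hyper_overrides:
            hyper = replace(hyper, n_residual_factors=1)
        self.hyper = hyper
        self.covariates = covariates if covariates is not None else Covariates(
            np.zeros((self.expression.n_cells, 0))
        )
        if self.covariates.X.shape[0] not in (0, self.expression.n_cells):
            raise ValueError("covariate rows do not match cell count")
        self.allele_data = None
        self._allele_log_lik = None
        if allele_data is not None:
            from .allele import allele_log_likelihood_matrix, harmonize_allele_cells

            allele_data = harmonize_allele_cells(allele_data, self.expression.cell_ids)
            allele_data = allele_data.filter_usable()
            self.allele_data = allele_data
            if allele_data.n_variants:
                if allele_data.variant_copy_number.shape[1] != self.clone_profile.n_clones:
                    raise ValueError(
                        "variant copy-number table clone count does not match profile"
                    )
                self._allele_log_lik = allele_log_likelihood_matrix(allele_data)

    @classmethod
    def from_dataframes(
        cls,
        counts_df,
        copy_number_df,
        covariates_df=None,
        **hyper_overrides,
    ) -> "CloneAssignModel":
        """Build from a cells×genes counts DataFrame and a genes×clones
        copy-number DataFrame (both indexed by ids)."""
        expr = ExpressionCounts(
            counts=counts_df.to_numpy(),
            cell_ids=counts_df.index.to_numpy(),
            gene_ids=counts_df.columns.to_numpy(),
        )
        prof = CloneProfile(
            copy_number=copy_number_df.to_numpy(),
            clone_labels=copy_number_df.columns.to_numpy(),
            gene_ids=copy_number_df.index.to_numpy(),
        )
        cov = None
        if covariates_df is not None:
            cov = Covariates(covariates_df.loc[counts_df.index].to_numpy())
        return cls(expr, prof, covariates=cov, **hyper_overrides)

    @property
    def dosage(self) -> np.ndarray:
        """G×C matrix of dosage factors f(lambda_gc)."""
        return dosage_function(self.clone_profile.copy_number, self.hyper.zeta)

    def fit(self, seed: int | None = None, verbose: bool = False):
        """Run variational inference; returns a
        :class:`~dosealign.results.CloneAssignResults`."""
        from .inference import fit as _fit

        if seed is None:
            seed = self.hyper.random_seed
        return _fit(self, seed=seed, verbose=verbose)
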