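import numpy as np
import pytest

from dosealign import (
    CloneProfile,
    Covariates,
    ExpressionCounts,
    ModelHyperparams,
    VariationalState,
)
from dosealign.model import rbf_centers


def make_state(n, g, c, q=1, p=0, m=5, seed=0, counts_range=(0, 50)):
    """Random but valid variational state for direct model-math tests."""
    rng = np.random.default_rng(seed)
    nu = rng.standard_normal(g) * 0.5
    nu[0] = 0.0
    rho = np.abs(rng.standard_normal(g)) * 0.1 + 0.05
    rho[0] = 0.0
    centers, b = rbf_centers(np.array(counts_range, dtype=float), m)
    phi = rng.dirichlet(np.ones(c), size=n)
    return VariationalState(
        phi=phi,
        nu=nu,
        rho=rho,
        psi=rng.standard_normal((n, q)) * 0.3,
        W=rng.standard_normal((g, q)) * 0.2,
        chi=np.abs(rng.standard_normal(q)) + 0.5,
        B=rng.standard_normal((g, p)) * 0.1,
        a=np.abs(rng.standard_normal(m)) + 0.5,
        s=rng.uniform(50, 200, size=n),
        rbf_centers=centers,
        rbf_bandwidth=b,
    )


@pytest.fixture
def tiny_expression():
    rng = np.random.default_rng(42)
    counts = rng.poisson(3.0, size=(5, 8))
    counts[0, 0] = 2  # keep the anchor gene expressed
    return ExpressionCounts(
        counts=counts,
        cell_ids=np.array([f"c{i}" for i in range(5)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(8)], dtype=object),
        gene_chromosome=np.array(
            ["chr1"] * 4 + ["chr2"] * 4, dtype=object
        ),
    )


@pytest.fixture
def tiny_profile():
    lam = np.full((8, 2), 2, dtype=np.int64)
    lam[4:, 1] = 3
    return CloneProfile(
        copy_number=lam,
        clone_labels=np.array(["A", "B"], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(8)], dtype=object),
    )


@pytest.fixture
def default_hyper():
    return ModelHyperparams(n_residual_factors=1, n_rbf_bases=5)


@pytest.fixture
def no_covariates():
    return Covariates(np.zeros((5, 0)))
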