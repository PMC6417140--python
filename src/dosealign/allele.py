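"""Allelic-imbalance likelihood at germline heterozygous SNVs.

In a region where a clone lost one allele (copy number 1, LOH) the
RNA allelic ratio at an expressed heterozygous SNV collapses toward 0 or 1,
whereas in a retained-heterozygous region (copy number 2) it sits near 1/2.
The per-variant observation model is beta-binomial:

    D_HET(a, r) = BetaBinomial(a; a + r, alpha=2,   beta=2)
    D_LOH(a, r) = 1/2 BetaBinomial(a; a + r, alpha=0.1, beta=1.9)
                + 1/2 BetaBinomial(a; a + r, alpha=1.9, beta=0.1)

with the clone's variant-level copy number selecting D_LOH (copy 1) or D_HET
(copy 2). These parameters are fixed calibration constants, never fitted.
The variant terms are conditionally independent given the clone, so they add
an N×C matrix of log-likelihood offsets to the expression model's
per-cell-per-clone log-likelihood. Assumes no copy-neutral LOH; if that is
suspected, fit from expression alone.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import betabinom

from .data import AlleleData

__all__ = [
    "betabinom_log_mass",
    "allele_log_likelihood",
    "allele_log_likelihood_matrix",
    "augment_log_joint",
    "harmonize_allele_cells",
]


def betabinom_log_mass(k, n, alpha: float, beta: float):
    """Exact beta-binomial log mass of ``k`` successes in ``n`` trials."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if (k_arr < 0).any() or (k_arr > n_arr).any():
        raise ValueError("require 0 <= k <= n")
    out = betabinom.logpmf(k_arr, n_arr, alpha, beta)
    if np.isscalar(k) and np.isscalar(n):
        return float(out)
    return out


def _log_d_het(a, r):
    return betabinom_log_mass(a, np.asarray(a) + np.asarray(r), 2.0, 2.0)


def _log_d_loh(a, r):
    n = np.asarray(a) + np.asarray(r)
    lo = betabinom.logpmf(a, n, 0.1, 1.9)
    hi = betabinom.logpmf(a, n, 1.9, 0.1)
    return np.logaddexp(lo, hi) - np.log(2.0)


def allele_log_likelihood(a, r, lam):
    """Log-likelihood of alt/ref counts at one variant given the clone's
    copy number there: D_LOH when ``lam == 1``, D_HET when ``lam == 2``."""
    lam_arr = np.asarray(lam)
    if not np.all((lam_arr == 1) | (lam_arr == 2)):
        raise RuntimeError(
            "allele likelihood reached with copy number outside {1, 2}; "
            "such variants must be filtered upstream"
        )
    het = _log_d_het(a, r)
    loh = _log_d_loh(a, r)
    out = np.where(lam_arr == 1, loh, het)
    if np.isscalar(lam) and np.isscalar(a):
        return float(out)
    return out


def allele_log_likelihood_matrix(allele: AlleleData) -> np.ndarray:
    """N×C matrix of summed variant log-likelihoods per cell and clone.

    A variant with zero coverage in a cell contributes its exact log-mass at
    zero trials, which is 0 for both D_HET and D_LOH (the single outcome of
    zero trials has probability one), so uncovered variants are neutral.
    """
    n, v = allele.alt.shape
    c = allele.variant_copy_number.shape[1]
    out = np.zeros((n, c))
    if v == 0:
        return out
    a = allele.alt
    r = allele.ref
    loh = _log_d_loh(a, r)  # N×V
    het = _log_d_het(a, r)
    for ci in range(c):
        is_loh = allele.variant_copy_number[:, ci] == 1  # V
        out[:, ci] = loh[:, is_loh].sum(axis=1) + het[:, ~is_loh].sum(axis=1)
    return out


def augment_log_joint(base_log_lik: np.ndarray, allele: AlleleData) -> np.ndarray:
    """Add the allele term to an N×C expression log-likelihood matrix."""
    base = np.asarray(base_log_lik, dtype=np.float64)
    extra = allele_log_likelihood_matrix(allele)
    if extra.shape != base.shape:
        raise ValueError(
            f"allele term shape {extra.shape} does not match base {base.shape}"
        )
    return base + extra


def harmonize_allele_cells(allele: AlleleData, cell_ids) -> AlleleData:
    """Reorder allele rows to the expression cell order; every expression
    cell must be present."""
    index = {cid: i for i, cid in enumerate(allele.cell_ids)}
    missing = [cid for cid in cell_ids if cid not in index]
    if missing:
        raise ValueError(f"allele data missing cells: {missing[:5]}")
    order = np.array([index[cid] for cid in cell_ids], dtype=np.int64)
    return AlleleData(
        alt=allele.alt[order],
        ref=allele.ref[order],
        variant_copy_number=allele.variant_copy_number,
        variant_ids=allele.variant_ids,
        cell_ids=np.asarray(cell_ids, dtype=object),
    )
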