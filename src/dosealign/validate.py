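"""Model validation: held-out-chromosome prediction and gene-selection
robustness.

``heldout_validate`` asks whether the inferred clone assignments carry real
predictive information: the model is refitted without the genes on held-out
chromosomes, each cell's MAP clone is used to predict the held-out expression
through the dosage mean, and the prediction RMSE (on per-gene z-scored log
expression) is compared against a null distribution obtained by permuting the
assignment vector.

``gene_selection_robustness`` refits after dropping genes — either the least
variable fraction (in log-expression space, deterministic) or a random
fraction over replicates — and scores the per-clone precision and recall of
the reduced-gene MAP assignments treating the full-gene fit as truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_score, recall_score

from .data import CloneProfile, ExpressionCounts
from .model import CloneAssignModel, dosage_function

__all__ = ["HeldoutResult", "heldout_validate", "gene_selection_robustness"]


@dataclass
class HeldoutResult:
    rmse_observed: float
    rmse_null: np.ndarray
    p_value: float
    held_out_gene_ids: np.ndarray
    map_clone_index: np.ndarray

    def __post_init__(self):
        assert 0.0 < self.p_value <= 1.0


def _zscore_log(mat: np.ndarray, size: np.ndarray) -> np.ndarray:
    """Per-gene z-score of log1p size-factor-normalized values."""
    norm = mat / size[:, None] * np.median(size)
    logn = np.log1p(norm)
    mean = logn.mean(axis=0)
    sd = logn.std(axis=0)
    sd[sd == 0] = 1.0
    return (logn - mean) / sd


def _predict_heldout(y_held: np.ndarray, lam_held: np.ndarray,
                     assign: np.ndarray, zeta: int) -> np.ndarray:
    """Dosage-model prediction of held-out counts given clone assignments.

    Per-copy expression for held-out genes cannot come from the fit (they
    were excluded), so it is estimated by pooled-mean normalization: the
    depth-normalized count of each gene divided by its dosage factor under
    each cell's assigned clone, averaged over cells.
    """
    s_held = y_held.sum(axis=1).astype(np.float64)
    s_held = np.maximum(s_held, 1.0)
    f = dosage_function(lam_held, zeta)  # G_h × C
    f_cells = f[:, assign].T  # N × G_h
    mu_hat = np.mean((y_held / s_held[:, None]) / f_cells, axis=0)
    mu_hat = np.maximum(mu_hat, 1e-12)
    weights = mu_hat * f_cells
    return s_held[:, None] * weights / weights.sum(axis=1, keepdims=True)


def heldout_validate(
    expression: ExpressionCounts,
    clone_profile: CloneProfile,
    held_out_chroms,
    n_permutations: int = 999,
    seed: int | None = None,
    assignments: np.ndarray | None = None,
    fit_seed: int | None = None,
    **hyper_overrides,
) -> HeldoutResult:
    """Permutation test of held-out-chromosome predictive accuracy.

    Fits on all genes except those on ``held_out_chroms`` (unless explicit
    0-based clone ``assignments`` are supplied), predicts held-out expression
    from each cell's MAP clone, and scores RMSE on z-scored log expression
    against ``n_permutations`` random permutations of the assignment vector.
    Smaller RMSE is better; the one-sided p-value uses the add-one rule and
    is therefore never smaller than ``1 / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1 for the p-value to be defined")
    if expression.gene_chromosome is None:
        raise ValueError("expression lacks gene_chromosome annotation")
    held_out_chroms = set(np.atleast_1d(held_out_chroms).tolist())
    held = np.array([ch in held_out_chroms for ch in expression.gene_chromosome])
    if held.sum() == 0:
        raise ValueError(f"no genes on held-out chromosomes {sorted(held_out_chroms)}")

    # align profile to expression gene order for the split
    cn_index = {gid: i for i, gid in enumerate(clone_profile.gene_ids)}
    if any(gid not in cn_index for gid in expression.gene_ids):
        raise ValueError("expression genes missing from clone profile; harmonize first")
    order = np.array([cn_index[gid] for gid in expression.gene_ids])
    lam = clone_profile.copy_number[order]
    if not (np.ptp(lam[held], axis=1) > 0).any():
        raise ValueError(
            "held-out chromosomes contain no gene with inter-clone "
            "copy-number difference; the test is undefined"
        )

    zeta = hyper_overrides.get("zeta", 6)
    if assignments is None:
        model = CloneAssignModel(
            expression.subset_genes(~held),
            clone_profile.subset_genes(order[~held]),
            **hyper_overrides,
        )
        res = model.fit(seed=fit_seed)
        assignments = np.argmax(res.state.phi, axis=1)
    else:
        assignments = np.asarray(assignments, dtype=np.int64)
        if assignments.shape != (expression.n_cells,):
            raise ValueError("assignments length does not match cell count")

    y_held = expression.counts[:, held].astype(np.float64)
    lam_held = lam[held]
    s_held = np.maximum(y_held.sum(axis=1).astype(np.float64), 1.0)
    z_obs = _zscore_log(y_held, s_held)

    def rmse_for(assign):
        pred = _predict_heldout(y_held, lam_held, assign, zeta)
        z_pred = _zscore_log(pred, s_held)
        return float(np.sqrt(np.mean((z_obs - z_pred) ** 2)))

    rmse_observed = rmse_for(assignments)
    rng = np.random.default_rng(seed)
    rmse_null = np.array(
        [rmse_for(rng.permutation(assignments)) for _ in range(n_permutations)]
    )
    p = (1.0 + float((rmse_null <= rmse_observed).sum())) / (1.0 + n_permutations)
    return HeldoutResult(
        rmse_observed=rmse_observed,
        rmse_null=rmse_null,
        p_value=p,
        held_out_gene_ids=expression.gene_ids[held],
        map_clone_index=assignments,
    )


def _log_expression_variance(counts: np.ndarray) -> np.ndarray:
    size = np.maximum(counts.sum(axis=1).astype(np.float64), 1.0)
    logn = np.log1p(counts / size[:, None] * np.median(size))
    return logn.var(axis=0)


def gene_selection_robustness(
    expression: ExpressionCounts,
    clone_profile: CloneProfile,
    drop_fractions=(0.3, 0.5, 0.7, 0.9),
    mode: str = "random",
    replicates: int = 10,
    seed: int | None = None,
    fit_seed: int | None = None,
    reference=None,
    **hyper_overrides,
) -> pd.DataFrame:
    """Stability of clone assignments under gene removal.

    mode "random": drop the given fraction of genes uniformly at random,
    ``replicates`` times per fraction. mode "least-variable": drop the bottom
    fraction by variance in log-expression space (deterministic; one
    replicate). Returns one row per (fraction, replicate, clone) with the
    precision and recall of the reduced fit's MAP assignments against the
    full-gene fit, plus overall concordance. A condition where the reduced
    gene set loses all inter-clone copy-number differences is flagged and
    scored as missing.
    """
    if mode not in ("random", "least-variable"):
        raise ValueError("mode must be 'random' or 'least-variable'")
    for frac in drop_fractions:
        if not (0 <= frac < 1):
            raise ValueError("drop fractions must lie in [0, 1)")
    if reference is None:
        full_model = CloneAssignModel(expression, clone_profile, **hyper_overrides)
        reference = full_model.fit(seed=fit_seed)
    ref_map = np.argmax(reference.state.phi, axis=1)
    clone_labels = clone_profile.clone_labels
    n_clones = clone_profile.n_clones
    g = expression.n_genes

    if mode == "least-variable":
        replicates = 1
        variance_order = np.argsort(_log_expression_variance(expression.counts))

    rng = np.random.default_rng(seed)
    rows = []
    for frac in drop_fractions:
        n_drop = int(round(frac * g))
        for rep in range(replicates):
            if frac == 0:
                new_map, failed = ref_map, False
            else:
                if mode == "least-variable":
                    drop_idx = variance_order[:n_drop]
                else:
                    drop_idx = rng.choice(g, size=n_drop, replace=False)
                keep = np.ones(g, dtype=bool)
                keep[drop_idx] = False
                failed = False
                try:
                    model = CloneAssignModel(
                        expression.subset_genes(keep),
                        clone_profile,
                        **hyper_overrides,
                    )
                    res = model.fit(seed=fit_seed)
                    new_map = np.argmax(res.state.phi, axis=1)
                except (ValueError, FloatingPointError):
                    failed = True
                    new_map = None
            concordance = (
                float(np.mean(new_map == ref_map)) if not failed else float("nan")
            )
            for c in range(n_clones):
                if failed:
                    prec = rec = float("nan")
                else:
                    prec = precision_score(ref_map == c, new_map == c, zero_division=0)
                    rec = recall_score(ref_map == c, new_map == c, zero_division=0)
                rows.append({
                    "mode": mode,
                    "drop_fraction": frac,
                    "replicate": rep,
                    "clone": clone_labels[c],
                    "precision": prec,
                    "recall": rec,
                    "concordance": concordance,
                    "fit_failed": failed,
                })
    return pd.DataFrame(rows)
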