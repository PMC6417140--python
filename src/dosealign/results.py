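"""Fit results: assignment probabilities, diagnostics and summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CloneAssignResults"]


class CloneAssignResults:
    """Result of fitting a :class:`~dosealign.model.CloneAssignModel`.

    Attributes
    ----------
    state
        Final :class:`~dosealign.model.VariationalState` including the full
        ELBO trace.
    converged
        Whether the smoothed-ELBO convergence rule fired before the
        iteration cap; a non-converged fit is returned with a warning, not
        an exception.
    """

    def __init__(self, model, state, converged: bool, n_iterations: int):
        self.model = model
        self.state = state
        self.converged = bool(converged)
        self.n_iterations = int(n_iterations)

    @property
    def elbo_trace(self) -> np.ndarray:
        return np.asarray(self.state.elbo_trace, dtype=np.float64)

    @property
    def clone_labels(self) -> np.ndarray:
        return self.model.clone_profile.clone_labels

    @property
    def assignment_probabilities(self) -> pd.DataFrame:
        """N×C posterior clone-assignment probabilities phi."""
        return pd.DataFrame(
            self.state.phi,
            index=pd.Index(self.model.expression.cell_ids, name="cell_id"),
            columns=self.clone_labels,
        )

    @property
    def map_clone(self) -> np.ndarray:
        """Per-cell maximum-a-posteriori clone label; ties break to the
        lowest clone index."""
        return self.clone_labels[np.argmax(self.state.phi, axis=1)]

    @property
    def max_probability(self) -> np.ndarray:
        return self.state.phi.max(axis=1)

    def clone_prevalence(self) -> pd.Series:
        """Fraction of cells MAP-assigned to each clone."""
        labels = pd.Categorical(self.map_clone, categories=self.clone_labels)
        return labels.value_counts() / len(self.map_clone)

    def predict_expected_counts(self, clone=None) -> np.ndarray:
        """Expected counts per cell under a given clone label (or each
        cell's MAP clone when ``clone`` is None)."""
        from .model import expected_counts

        labels = list(self.clone_labels)
        if clone is not None:
            c = labels.index(clone)
            return expected_counts(self.state, c, self.model.clone_profile,
                                   self.model.covariates, self.model.hyper)
        out = np.empty(self.model.expression.counts.shape, dtype=np.float64)
        map_idx = np.argmax(self.state.phi, axis=1)
        for c in np.unique(map_idx):
            rows = map_idx == c
            m = expected_counts(self.state, int(c), self.model.clone_profile,
                                self.model.covariates, self.model.hyper)
            out[rows] = m[rows]
        return out

    def plot_elbo(self, ax=None):
        """ELBO trace over iterations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.elbo_trace) + 1), self.elbo_trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("ELBO")
        return ax

    def summary(self) -> str:
        n, g = self.model.expression.counts.shape
        lines = [
            "Clone assignment (copy-number dosage model)",
            "=" * 46,
            f"cells: {n}    genes: {g}    clones: {self.model.clone_profile.n_clones}",
            f"residual factors Q: {self.model.hyper.n_residual_factors}"
            f"    dosage cap zeta: {self.model.hyper.zeta}",
            f"iterations: {self.n_iterations}"
            f"    converged: {self.converged}",
            f"final ELBO: {self.elbo_trace[-1]:.2f}",
            "",
            "MAP clone prevalence:",
        ]
        for label, frac in self.clone_prevalence().items():
            lines.append(f"  {label}: {frac:.3f}")
        mean_conf = float(self.max_probability.mean())
        lines.append(f"mean MAP probability: {mean_conf:.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<CloneAssignResults cells={self.state.phi.shape[0]} "
                f"clones={self.state.phi.shape[1]} converged={self.converged}>")
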