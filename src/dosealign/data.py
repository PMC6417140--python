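"""Input containers and harmonization.

The model consumes three aligned pieces of data: an N×G matrix of raw
scRNA-seq counts, a G×C matrix of clone-specific copy numbers derived from
scDNA-seq, and (optionally) an N×P matrix of known per-cell covariates.
These containers validate the invariants the model relies on (integral
non-negative counts, unique identifiers, at least one copy-number-variable
gene) and `harmonize` intersects the expression and copy-number gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger("dosealign")

__all__ = [
    "ExpressionCounts",
    "CloneProfile",
    "Covariates",
    "AlleleData",
    "harmonize",
]


def _check_unique(ids, what: str) -> None:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids.tolist())) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise ValueError(f"duplicate {what} ids: {dupes}")


def _as_dense_int_matrix(counts, what: str) -> np.ndarray:
    if sparse.issparse(counts):
        counts = counts.toarray()
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise ValueError(f"{what} must be 2-dimensional, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{what} contains non-finite entries")
    if (arr < 0).any():
        raise ValueError(f"{what} contains negative entries")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{what} contains non-integer entries")
    return np.asarray(np.round(arr), dtype=np.int64)


@dataclass
class ExpressionCounts:
    """Raw scRNA-seq counts for N cells × G genes.

    Parameters
    ----------
    counts
        N×G non-negative integer matrix of reads or UMIs (dense or sparse).
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    gene_chromosome
        Optional chromosome label per gene (opaque strings), used for
        held-out-chromosome validation.
    gene_position
        Optional 1-based gene start positions for ordering/plotting.
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_chromosome: np.ndarray | None = None
    gene_position: np.ndarray | None = None

    def __post_init__(self):
        self.counts = _as_dense_int_matrix(self.counts, "counts")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if n < 1 or g < 2:
            raise ValueError(f"need N >= 1 cells and G >= 2 genes, got N={n}, G={g}")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} count rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} count columns")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.gene_chromosome is not None:
            self.gene_chromosome = np.asarray(self.gene_chromosome, dtype=object)
            if len(self.gene_chromosome) != g:
                raise ValueError("gene_chromosome length mismatch")
        if self.gene_position is not None:
            self.gene_position = np.asarray(self.gene_position, dtype=np.int64)
            if len(self.gene_position) != g:
                raise ValueError("gene_position length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask_or_index) -> "ExpressionCounts":
        idx = np.asarray(mask_or_index)
        return ExpressionCounts(
            counts=self.counts[:, idx],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[idx],
            gene_chromosome=None if self.gene_chromosome is None else self.gene_chromosome[idx],
            gene_position=None if self.gene_position is None else self.gene_position[idx],
        )


@dataclass
class CloneProfile:
    """Clone-specific integer copy numbers for G genes × C clones."""

    copy_number: np.ndarray
    clone_labels: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self):
        self.copy_number = _as_dense_int_matrix(self.copy_number, "copy_number")
        self.clone_labels = np.asarray(self.clone_labels, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        g, c = self.copy_number.shape
        if c < 2:
            raise ValueError(f"need C >= 2 clones, got C={c}")
        if len(self.clone_labels) != c:
            raise ValueError("clone label count mismatch")
        if len(self.gene_ids) != g:
            raise ValueError("gene id count mismatch")
        _check_unique(self.clone_labels, "clone")
        _check_unique(self.gene_ids, "gene")
        if not (np.ptp(self.copy_number, axis=1) > 0).any():
            raise ValueError(
                "all clones have identical copy-number profiles: "
                "clone assignment is unidentifiable"
            )

    @property
    def n_genes(self) -> int:
        return self.copy_number.shape[0]

    @property
    def n_clones(self) -> int:
        return self.copy_number.shape[1]

    def subset_genes(self, mask_or_index) -> "CloneProfile":
        idx = np.asarray(mask_or_index)
        return CloneProfile(
            copy_number=self.copy_number[idx, :],
            clone_labels=self.clone_labels,
            gene_ids=self.gene_ids[idx],
        )


@dataclass
class Covariates:
    """Known per-cell covariates (N×P real matrix); P = 0 means absent."""

    X: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("covariate matrix must be 2-dimensional")
        if self.X.size and not np.isfinite(self.X).all():
            raise ValueError("covariate matrix contains non-finite entries")

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


@dataclass
class AlleleData:
    """Alt/ref counts at germline heterozygous SNVs plus variant-level clone
    copy number.

    Only variants whose copy number is 1 (LOH) or 2 (retained heterozygous)
    in *every* clone are usable by the allelic-imbalance likelihood; others
    are dropped by :meth:`filter_usable` with a logged count.
    """

    alt: np.ndarray
    ref: np.ndarray
    variant_copy_number: np.ndarray
    variant_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self):
        self.alt = _as_dense_int_matrix(self.alt, "alt counts")
        self.ref = _as_dense_int_matrix(self.ref, "ref counts")
        self.variant_copy_number = _as_dense_int_matrix(
            self.variant_copy_number, "variant copy number"
        )
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.alt.shape != self.ref.shape:
            raise ValueError("alt and ref count matrices differ in shape")
        n, v = self.alt.shape
        if len(self.cell_ids) != n:
            raise ValueError("cell id count mismatch in allele data")
        if len(self.variant_ids) != v:
            raise ValueError("variant id count mismatch in allele data")
        if self.variant_copy_number.shape[0] != v:
            raise ValueError("variant copy-number table row count mismatch")
        _check_unique(self.variant_ids, "variant")
        zero_cov = (self.alt.sum(axis=0) + self.ref.sum(axis=0)) == 0
        if zero_cov.any():
            logger.info("%d variant(s) have zero coverage in all cells", zero_cov.sum())

    @property
    def n_variants(self) -> int:
        return self.alt.shape[1]

    def filter_usable(self) -> "AlleleData":
        """Keep variants with copy number in {1, 2} for every clone."""
        ok = np.all(
            (self.variant_copy_number == 1) | (self.variant_copy_number == 2), axis=1
        )
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info(
                "dropping %d variant(s) with copy number outside {1,2} in some clone",
                n_drop,
            )
        return AlleleData(
            alt=self.alt[:, ok],
            ref=self.ref[:, ok],
            variant_copy_number=self.variant_copy_number[ok, :],
            variant_ids=self.variant_ids[ok],
            cell_ids=self.cell_ids,
        )


def harmonize(
    expression: ExpressionCounts, clone_profile: CloneProfile
) -> tuple[ExpressionCounts, CloneProfile]:
    """Intersect gene sets by exact gene-id match, preserving expression order.

    Genes present in only one input are dropped with a logged count; an empty
    intersection or a post-harmonization profile with no copy-number-variable
    gene raises.
    """
    cn_index = {g: i for i, g in enumerate(clone_profile.gene_ids)}
    keep_expr = np.array([g in cn_index for g in expression.gene_ids], dtype=bool)
    n_dropped_expr = int((~keep_expr).sum())
    shared = expression.gene_ids[keep_expr]
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} gene(s) shared between expression and copy-number inputs"
        )
    n_dropped_cn = clone_profile.n_genes - len(shared)
    if n_dropped_expr or n_dropped_cn:
        logger.info(
            "harmonization dropped %d expression gene(s) and %d copy-number gene(s)",
            n_dropped_expr,
            n_dropped_cn,
        )
    expr = expression.subset_genes(keep_expr)
    order = np.array([cn_index[g] for g in shared], dtype=np.int64)
    prof = clone_profile.subset_genes(order)
    return expr, prof
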