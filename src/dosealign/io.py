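"""Readers and writers for the on-disk formats.

Expression counts travel either as a CellRanger-style Matrix Market triplet
directory (``matrix.mtx`` with genes as rows and cells as columns, plus
``genes.tsv``/``features.tsv`` and ``barcodes.tsv``) or as a dense CSV with
cell ids in the first column and gene ids in the header. Clone profiles and
covariates are plain CSV/TSV tables; allele counts are a pair of cell×variant
Matrix Market files with id sidecars and a variant×clone CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data import AlleleData, CloneProfile, Covariates, ExpressionCounts

logger = logging.getLogger("dosealign")

__all__ = [
    "read_expression",
    "write_expression",
    "read_clone_profile",
    "write_clone_profile",
    "read_covariates",
    "read_allele_data",
    "write_assignments",
    "write_simulated_dataset",
    "write_run_config",
]


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def _find(directory: Path, names) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {names} found in {directory}")


def read_expression(path) -> ExpressionCounts:
    """Read counts from an MTX triplet directory or a dense CSV.

    The triplet layout stores genes as matrix rows (CellRanger convention);
    the returned container is cells × genes. Gene annotation files may carry
    columns gene_id[, symbol][, chromosome][, position].
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find(path, ["matrix.mtx"])
        genes_file = _find(path, ["genes.tsv", "features.tsv"])
        barcodes_file = _find(path, ["barcodes.tsv"])
        mat = spio.mmread(mtx)  # genes × cells, 1-based triplet indices
        genes = pd.read_csv(genes_file, sep="\t", header=None)
        barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)
        counts = np.asarray(sparse.coo_matrix(mat).todense()).T
        if counts.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix {mat.shape} (genes × cells) does not match "
                f"{genes_file.name} ({len(genes)} rows) and "
                f"{barcodes_file.name} ({len(barcodes)} rows)"
            )
        chrom = genes.iloc[:, 2].to_numpy() if genes.shape[1] > 2 else None
        pos = genes.iloc[:, 3].to_numpy() if genes.shape[1] > 3 else None
        return ExpressionCounts(
            counts=counts,
            cell_ids=barcodes.iloc[:, 0].to_numpy(),
            gene_ids=genes.iloc[:, 0].to_numpy(),
            gene_chromosome=chrom,
            gene_position=pos,
        )
    df = pd.read_csv(path, index_col=0)
    return ExpressionCounts(
        counts=df.to_numpy(),
        cell_ids=df.index.to_numpy(),
        gene_ids=df.columns.to_numpy(),
    )


def write_expression(expression: ExpressionCounts, directory) -> None:
    """Write the CellRanger-like triplet layout (genes × cells matrix.mtx)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(expression.counts.T)
    spio.mmwrite(directory / "matrix.mtx", mat, field="integer")
    genes = pd.DataFrame({"gene_id": expression.gene_ids,
                          "symbol": expression.gene_ids})
    if expression.gene_chromosome is not None:
        genes["chromosome"] = expression.gene_chromosome
    if expression.gene_position is not None:
        genes["position"] = expression.gene_position
    genes.to_csv(directory / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(expression.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_clone_profile(path) -> CloneProfile:
    """Read a gene_id[, chromosome] + one-integer-column-per-clone table."""
    path = Path(path)
    df = _read_table(path)
    if df.columns[0] != "gene_id":
        df = df.rename(columns={df.columns[0]: "gene_id"})
    clone_cols = [c for c in df.columns[1:] if c != "chromosome"]
    if len(clone_cols) < 2:
        raise ValueError(f"{path} has {len(clone_cols)} clone column(s); need >= 2")
    values = df[clone_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.allclose(
        values, np.round(values)
    ):
        raise ValueError(f"{path} contains non-integer copy numbers")
    return CloneProfile(
        copy_number=values.astype(np.int64),
        clone_labels=np.asarray(clone_cols, dtype=object),
        gene_ids=df["gene_id"].to_numpy(),
    )


def write_clone_profile(profile: CloneProfile, path) -> None:
    df = pd.DataFrame(profile.copy_number, columns=profile.clone_labels)
    df.insert(0, "gene_id", profile.gene_ids)
    df.to_csv(path, index=False)


def read_covariates(path) -> tuple[Covariates, np.ndarray]:
    """Read an N×P covariate CSV (cell ids in the first column); returns the
    covariates and the cell id order they came in."""
    df = pd.read_csv(path, index_col=0)
    return Covariates(df.to_numpy(dtype=np.float64)), df.index.to_numpy()


def read_allele_data(directory) -> AlleleData:
    """Read alt.mtx / ref.mtx (cells × variants), variants.tsv, cells.tsv and
    variant_copy_number.csv (variant_id + one column per clone)."""
    directory = Path(directory)
    alt = np.asarray(sparse.coo_matrix(spio.mmread(directory / "alt.mtx")).todense())
    ref = np.asarray(sparse.coo_matrix(spio.mmread(directory / "ref.mtx")).todense())
    variants = pd.read_csv(directory / "variants.tsv", sep="\t", header=None)
    cells = pd.read_csv(directory / "cells.tsv", sep="\t", header=None)
    cn = pd.read_csv(directory / "variant_copy_number.csv", index_col=0)
    cn = cn.loc[variants.iloc[:, 0]]
    return AlleleData(
        alt=alt,
        ref=ref,
        variant_copy_number=cn.to_numpy(),
        variant_ids=variants.iloc[:, 0].to_numpy(),
        cell_ids=cells.iloc[:, 0].to_numpy(),
    )


def write_assignments(results, directory) -> None:
    """Write assignments.csv, elbo_trace.csv and the resolved run config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    probs = results.assignment_probabilities
    out = probs.copy()
    out.insert(0, "map_clone", results.map_clone)
    out["max_probability"] = results.max_probability
    out.to_csv(directory / "assignments.csv", float_format="%.6f")
    pd.DataFrame({
        "iteration": np.arange(1, len(results.elbo_trace) + 1),
        "elbo": results.elbo_trace,
    }).to_csv(directory / "elbo_trace.csv", index=False)
    hyper = results.model.hyper
    config = {k: getattr(hyper, k) for k in hyper.__dataclass_fields__}
    config.update({
        "n_cells": int(results.state.phi.shape[0]),
        "n_genes": int(results.model.expression.n_genes),
        "n_clones": int(results.state.phi.shape[1]),
        "converged": results.converged,
        "n_iterations": results.n_iterations,
    })
    write_run_config(config, directory / "resolved_config.json")


def write_run_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, default=str)
        fh.write("\n")


def read_run_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_simulated_dataset(sim, directory) -> None:
    """Write counts triplet, clone_profile.csv and true_clones.csv."""
    directory = Path(directory)
    write_expression(sim.expression, directory / "counts")
    write_clone_profile(sim.clone_profile, directory / "clone_profile.csv")
    pd.DataFrame({
        "cell_id": sim.expression.cell_ids,
        "true_clone": sim.true_clone,
    }).to_csv(directory / "true_clones.csv", index=False)
    pd.DataFrame({
        "gene_id": sim.expression.gene_ids,
        "dosage_active": sim.dosage_mask.astype(int),
    }).to_csv(directory / "dosage_mask.csv", index=False)
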