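"""Quality filtering, normalization-state detection and log-normalization.

Genes expressed in fewer than ``gene_min_cell_fraction`` of cells and cells
with fewer than ``cell_min_genes`` detected genes are removed. Raw counts
(detected as all-integer values) are scaled by median-library-size factors
before the shared log(x+1) transform; already-normalized input only gets the
log transform. Within-cell value order is preserved either way, which is
what the downstream rank-based activity scores depend on.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import ExpressionMatrix

log = logging.getLogger("ctsr")


@dataclass
class PreprocessParams:
    gene_min_cell_fraction: float = 0.001
    cell_min_genes: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.gene_min_cell_fraction < 1:
            raise ValueError("gene_min_cell_fraction must be in (0, 1)")
        if self.cell_min_genes < 0:
            raise ValueError("cell_min_genes must be >= 0")


def filter_matrix(em: ExpressionMatrix, params: PreprocessParams | None = None) -> ExpressionMatrix:
    """Apply the gene filter, then the cell filter (single pass each)."""
    params = params or PreprocessParams()
    nonzero = em.values != 0
    gene_frac = nonzero.sum(axis=1) / em.n_cells
    keep_genes = gene_frac >= params.gene_min_cell_fraction
    if not keep_genes.any():
        raise ValueError(
            f"gene filter removed all {em.n_genes} genes "
            f"(threshold {params.gene_min_cell_fraction})"
        )
    nonzero = nonzero[keep_genes]
    genes_per_cell = nonzero.sum(axis=0)
    keep_cells = genes_per_cell >= params.cell_min_genes
    if not keep_cells.any():
        raise ValueError(
            f"cell filter removed all {em.n_cells} cells "
            f"(threshold {params.cell_min_genes} genes/cell)"
        )
    log.info(
        "filter: kept %d/%d genes, %d/%d cells",
        int(keep_genes.sum()), em.n_genes, int(keep_cells.sum()), em.n_cells,
    )
    return ExpressionMatrix(
        em.values[np.ix_(keep_genes, keep_cells)],
        [g for g, k in zip(em.gene_ids, keep_genes) if k],
        [c for c, k in zip(em.cell_ids, keep_cells) if k],
        em.normalized,
        em.log_transformed,
    )


def detect_normalization(em: ExpressionMatrix, tol: float = 1e-9) -> bool:
    """True when the matrix looks normalized (any non-integer nonzero value)."""
    vals = em.values[em.values != 0]
    if vals.size == 0:
        return False
    return bool(np.any(np.abs(vals - np.round(vals)) >= tol))


def normalize_and_log(em: ExpressionMatrix, normalized: bool | None = None) -> ExpressionMatrix:
    """Median-library-size normalization (raw counts only) followed by log1p."""
    if em.log_transformed:
        raise ValueError("matrix is already log-transformed")
    if normalized is None:
        normalized = detect_normalization(em)
    values = em.values
    if not normalized:
        lib = values.sum(axis=0)
        if np.any(lib == 0):
            bad = [c for c, s in zip(em.cell_ids, lib) if s == 0]
            raise ValueError(f"cells with zero library size: {bad[:5]}")
        factors = lib / np.median(lib)
        values = values / factors[None, :]
    return ExpressionMatrix(
        np.log1p(values), em.gene_ids, em.cell_ids,
        normalized=True, log_transformed=True,
    )


def preprocess(em: ExpressionMatrix, params: PreprocessParams | None = None) -> ExpressionMatrix:
    """filter → detect normalization → normalize → log1p."""
    filtered = filter_matrix(em, params)
    return normalize_and_log(filtered)
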