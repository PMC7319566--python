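"""Cell clustering fallback, clustering-agreement indexes and DEG detection.

Clustering is deliberately pluggable: user-supplied labels always take
precedence in the pipeline, and the built-in fallback is PCA over the
top-variable genes followed by k-means. The agreement indexes (Rand,
adjusted Rand, Jaccard, Fowlkes–Mallows) are computed from pair counts on
the contingency table. DEGs come from a one-vs-rest two-sided Wilcoxon
rank-sum test (normal approximation with tie correction) with
Benjamini–Hochberg adjustment within each cell type.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.cluster import KMeans

from .types import CellLabeling, ExpressionMatrix

log = logging.getLogger("ctsr")


def cluster_cells(
    em: ExpressionMatrix,
    k: int,
    n_pcs: int = 10,
    n_top_genes: int = 2000,
    seed: int = 0,
) -> CellLabeling:
    """PCA + k-means fallback clusterer on the log-normalized matrix."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if em.n_cells < k:
        raise ValueError(f"cannot form {k} clusters from {em.n_cells} cells")
    variances = em.values.var(axis=1)
    order = np.argsort(-variances, kind="stable")[: min(n_top_genes, em.n_genes)]
    X = em.values[order].T  # cells x genes
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
    if n_comp >= 1:
        X = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assign = km.fit_predict(X)
    # renumber clusters by first appearance so output is order-stable
    remap: dict[int, int] = {}
    labels = []
    for a in assign:
        if a not in remap:
            remap[a] = len(remap) + 1
        labels.append(f"C{remap[a]}")
    return CellLabeling(list(em.cell_ids), labels)


@dataclass
class AgreementIndexes:
    rand: float
    adjusted_rand: float
    jaccard: float
    fowlkes_mallows: float


def _aligned_codes(a: CellLabeling, b: CellLabeling) -> tuple[np.ndarray, np.ndarray]:
    if set(a.cell_ids) != set(b.cell_ids):
        raise ValueError("labelings cover different cell sets")
    bmap = b.as_dict()
    la = pd.Categorical(a.labels).codes
    lb = pd.Categorical([bmap[c] for c in a.cell_ids]).codes
    return np.asarray(la), np.asarray(lb)


def clustering_agreement(a: CellLabeling, b: CellLabeling) -> AgreementIndexes:
    """Pair-counting agreement between two labelings of the same cells."""
    la, lb = _aligned_codes(a, b)
    n = la.size
    cont = pd.crosstab(la, lb).to_numpy()
    nij = cont.astype(float)
    sum_ij = (nij * (nij - 1) / 2).sum()        # same-same pairs a11
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    sum_a = (ai * (ai - 1) / 2).sum()           # a11 + a10
    sum_b = (bj * (bj - 1) / 2).sum()           # a11 + a01
    total = n * (n - 1) / 2
    a11 = sum_ij
    a10 = sum_a - sum_ij
    a01 = sum_b - sum_ij
    a00 = total - a11 - a10 - a01
    rand = (a11 + a00) / total
    jaccard = a11 / (a11 + a10 + a01) if (a11 + a10 + a01) > 0 else 1.0
    fm = a11 / np.sqrt(sum_a * sum_b) if sum_a > 0 and sum_b > 0 else 1.0
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    denom = max_index - expected
    ari = (a11 - expected) / denom if denom != 0 else 1.0
    return AgreementIndexes(float(rand), float(ari), float(jaccard), float(fm))


def find_degs(
    em: ExpressionMatrix,
    labeling: CellLabeling,
    deg_alpha: float = 0.05,
    lfc_min: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon DEG table with BH adjustment per cell type.

    Returns a DataFrame with columns gene_id, cell_type, log2_fold_change,
    p_value, adjusted_p, is_deg. Fold changes are log2 ratios of mean
    unlogged expression (expm1 of the log values) with a +1 pseudocount.
    """
    if len(labeling.label_set) < 2:
        raise ValueError("DEG detection needs at least two cell types")
    if labeling.cell_ids != em.cell_ids:
        raise ValueError("labeling must cover the matrix cells in order")
    lab = np.asarray(labeling.labels)
    frames = []
    raw = np.expm1(em.values)
    for ct in labeling.label_set:
        mask = lab == ct
        if mask.sum() < 3:
            log.warning("cell type %s has <3 cells; skipped in DEG detection", ct)
            continue
        x = em.values[:, mask]
        y = em.values[:, ~mask]
        # exact null for small tie-free samples, else tie-corrected normal
        res = stats.mannwhitneyu(
            x, y, axis=1, alternative="two-sided", method="auto"
        )
        p = np.asarray(res.pvalue, dtype=float)
        # constant genes: zero-variance statistic sits at the null center
        p[~np.isfinite(p)] = 1.0
        lfc = np.log2((raw[:, mask].mean(axis=1) + 1) / (raw[:, ~mask].mean(axis=1) + 1))
        adj = stats.false_discovery_control(p, method="bh")
        frames.append(pd.DataFrame({
            "gene_id": em.gene_ids,
            "cell_type": ct,
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": adj,
            "is_deg": (adj < deg_alpha) & (lfc >= lfc_min),
        }))
    if not frames:
        raise ValueError("no cell type had >= 3 cells")
    return pd.concat(frames, ignore_index=True)


def deg_coverage(regulon_genes, deg_table: pd.DataFrame, cell_type: str) -> float:
    """Fraction of a regulon's genes that are DEGs of its cell type."""
    genes = list(regulon_genes)
    if not genes:
        raise ValueError("empty regulon")
    sub = deg_table[(deg_table["cell_type"] == cell_type) & deg_table["is_deg"]]
    degs = set(sub["gene_id"])
    return sum(g in degs for g in genes) / len(genes)
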