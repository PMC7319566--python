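"""Regulon activity and cell-type specificity scoring.

RAS (regulon activity score): per cell, genes are ranked by expression
(rank 1 = highest, ties by gene index) and the regulon's recovery curve —
the count of regulon genes among the top-k genes for k = 1..K, with K the
top 5% of the ranking by default — is summed and divided by its maximum
achievable value, giving an AUC-style score in [0, 1] that depends only on
within-cell ranks.

RSS (regulon specificity score): the RAS vector normalized to a
distribution over cells is compared with the cell-type indicator
distribution via the Jensen–Shannon divergence (base-2 logs, so
JSD ∈ [0, 1]); RSS = 1 − sqrt(JSD) is 1 exactly when activity matches the
cell type's indicator and 0 when their supports are disjoint.

Significance: the observed RSS is compared against RSSs of random gene
sets of the same size (sampling without replacement), giving an empirical
p-value with the +1/(n+1) estimator, Bonferroni-adjusted by the number of
regulons in the same cell type. Regulons pass as cell-type-specific
(CTSR) at adjusted p < alpha and are named CT{n}-R{m}: n indexes the cell
type in label order, m ranks regulons by ascending empirical p (ties by
descending RSS, then TF name).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CellLabeling, ExpressionMatrix, Regulon

log = logging.getLogger("ctsr")


@dataclass
class RankMatrix:
    """Per-cell descending-expression ranks (1 = highest); ties by gene index."""

    ranks: np.ndarray  # genes x cells, int
    gene_ids: list[str]
    cell_ids: list[str]


def rank_genes_per_cell(em: ExpressionMatrix) -> RankMatrix:
    order = np.argsort(-em.values, axis=0, kind="stable")
    ranks = np.empty(em.values.shape, dtype=np.int64)
    cols = np.arange(em.n_cells)[None, :]
    ranks[order, cols] = np.arange(1, em.n_genes + 1)[:, None]
    return RankMatrix(ranks, list(em.gene_ids), list(em.cell_ids))


def _max_recovery_sum(g: int, K: int) -> int:
    # all g genes at the top: counts are min(k, g) for k = 1..K
    if g >= K:
        return K * (K + 1) // 2
    return g * (g + 1) // 2 + (K - g) * g


def _ras_from_rank_rows(rank_rows: np.ndarray, K: int) -> np.ndarray:
    """RAS per cell from the regulon genes' rank rows (g x cells)."""
    contrib = np.clip(K - rank_rows + 1, 0, None)
    return contrib.sum(axis=0) / _max_recovery_sum(rank_rows.shape[0], K)


def regulon_activity(
    rm: RankMatrix,
    regulon_genes,
    top_fraction: float = 0.05,
) -> np.ndarray:
    """Recovery-curve AUC of the regulon genes in each cell's top-K ranking."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n_genes = len(rm.gene_ids)
    K = max(1, math.ceil(top_fraction * n_genes))
    idx_map = {g: i for i, g in enumerate(rm.gene_ids)}
    rows = [idx_map[g] for g in regulon_genes if g in idx_map]
    n_missing = len(list(regulon_genes)) - len(rows)
    if n_missing:
        log.warning("%d regulon gene(s) absent from the matrix; dropped", n_missing)
    if not rows:
        raise ValueError("no regulon gene present in the matrix")
    return _ras_from_rank_rows(rm.ranks[rows], K)


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD with base-2 logs; bounded by [0, 1]."""
    m = 0.5 * (p + q)
    jsd = _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))
    return float(min(1.0, max(0.0, jsd)))


def regulon_specificity(
    ras: np.ndarray, labeling: CellLabeling, cell_type: str
) -> float:
    """RSS = 1 − sqrt(JSD(normalized RAS, cell-type indicator))."""
    ras = np.asarray(ras, dtype=float)
    if ras.size != len(labeling.cell_ids):
        raise ValueError("RAS vector and labeling cover different cells")
    if np.any(ras < 0):
        raise ValueError("RAS must be nonnegative")
    total = ras.sum()
    if total == 0:
        log.warning("all-zero RAS vector; RSS defined as 0")
        return 0.0
    mask = np.asarray([l == cell_type for l in labeling.labels], dtype=float)
    if mask.sum() == 0:
        raise ValueError(f"cell type {cell_type!r} has no cells")
    p = ras / total
    q = mask / mask.sum()
    return 1.0 - math.sqrt(jensen_shannon_divergence(p, q))


def _rss_many(ras_matrix: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise RSS of many RAS vectors against one indicator distribution."""
    totals = ras_matrix.sum(axis=1, keepdims=True)
    safe = np.where(totals == 0, 1.0, totals)
    p = ras_matrix / safe
    m = 0.5 * (p + q[None, :])

    def h2(x):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(x > 0, x * np.log2(np.where(x > 0, x, 1.0)), 0.0)
        return -t.sum(axis=1)

    jsd = np.clip(h2(m) - 0.5 * (h2(p) + h2(q[None, :])), 0.0, 1.0)
    rss = 1.0 - np.sqrt(jsd)
    rss[totals[:, 0] == 0] = 0.0
    return rss


def empirical_pvalue(
    rm: RankMatrix,
    regulon_genes,
    labeling: CellLabeling,
    cell_type: str,
    n_boot: int = 10000,
    seed: int = 0,
    top_fraction: float = 0.05,
    rss_obs: float | None = None,
) -> float:
    """Bootstrap p-value of the regulon's RSS against random gene sets.

    Gene sets of the regulon's size are drawn uniformly without replacement
    from all matrix genes; p = (1 + #{null RSS >= observed}) / (1 + n_boot).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    genes = [g for g in regulon_genes if g in set(rm.gene_ids)]
    g = len(genes)
    n_genes = len(rm.gene_ids)
    if g < 1:
        raise ValueError("no regulon gene present in the matrix")
    if g > n_genes:
        raise ValueError("regulon larger than the gene universe")
    if rss_obs is None:
        rss_obs = regulon_specificity(
            regulon_activity(rm, genes, top_fraction), labeling, cell_type
        )
    K = max(1, math.ceil(top_fraction * n_genes))
    contrib = np.clip(K - rm.ranks + 1, 0, None).astype(np.float64)
    max_sum = _max_recovery_sum(g, K)
    mask = np.asarray([l == cell_type for l in labeling.labels], dtype=float)
    q = mask / mask.sum()
    rng = np.random.default_rng(seed)
    n_exceed = 0
    chunk = max(1, min(n_boot, 512))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        keys = rng.random((b, n_genes))
        sets = np.argpartition(keys, g - 1, axis=1)[:, :g]
        ras_null = contrib[sets].sum(axis=1) / max_sum  # b x cells
        rss_null = _rss_many(ras_null, q)
        n_exceed += int((rss_null >= rss_obs - 1e-12).sum())
        done += b
    return (1 + n_exceed) / (1 + n_boot)


@dataclass
class ScoredRegulon:
    regulon: Regulon
    ras: np.ndarray
    rss: float
    p_empirical: float
    name: str = ""
    p_adjusted: float = 1.0
    is_ctsr: bool = False
    rank: int = 0


@dataclass
class RegulonScoreTable:
    """Final score table plus the per-regulon RAS matrix."""

    table: pd.DataFrame
    scored: list[ScoredRegulon] = field(default_factory=list)

    def ras_matrix(self, cell_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {s.name: s.ras for s in self.scored}, index=cell_ids
        ).T


def call_ctsrs(
    scored: list[ScoredRegulon],
    labeling: CellLabeling,
    alpha: float = 0.05,
) -> RegulonScoreTable:
    """Adjust p-values within cell types, flag CTSRs and assign CTn-Rm names."""
    if alpha not in (0.001, 0.01, 0.05):
        log.warning("non-standard CTSR alpha %g (standard: 0.001/0.01/0.05)", alpha)
    type_index = {ct: i + 1 for i, ct in enumerate(labeling.label_set)}
    by_type: dict[str, list[ScoredRegulon]] = {}
    for s in scored:
        by_type.setdefault(s.regulon.cell_type, []).append(s)
    for ct, group in by_type.items():
        group.sort(key=lambda s: (s.p_empirical, -s.rss, s.regulon.tf_name))
        n_in_type = len(group)
        for m, s in enumerate(group, start=1):
            s.rank = m
            s.p_adjusted = min(1.0, s.p_empirical * n_in_type)
            s.is_ctsr = s.p_adjusted < alpha
            s.name = f"CT{type_index[ct]}-R{m}"
            s.regulon.name = s.name
    ordered = sorted(scored, key=lambda s: (type_index[s.regulon.cell_type], s.rank))
    table = pd.DataFrame([
        {
            "name": s.name,
            "cell_type": s.regulon.cell_type,
            "tf": s.regulon.tf_name,
            "n_genes": len(s.regulon.genes),
            "rss": s.rss,
            "p_empirical": s.p_empirical,
            "p_adjusted": s.p_adjusted,
            "is_ctsr": s.is_ctsr,
        }
        for s in ordered
    ], columns=["name", "cell_type", "tf", "n_genes", "rss",
                "p_empirical", "p_adjusted", "is_ctsr"])
    return RegulonScoreTable(table, ordered)


def score_regulons(
    em: ExpressionMatrix,
    regulons: list[Regulon],
    labeling: CellLabeling,
    alpha: float = 0.05,
    n_boot: int = 10000,
    seed: int = 0,
    top_fraction: float = 0.05,
) -> RegulonScoreTable:
    """RAS → RSS → bootstrap p → CTSR calls for a list of regulons."""
    rm = rank_genes_per_cell(em)
    scored: list[ScoredRegulon] = []
    seeds = np.random.SeedSequence(seed).generate_state(max(1, len(regulons)))
    for i, reg in enumerate(regulons):
        ras = regulon_activity(rm, reg.genes, top_fraction)
        rss = regulon_specificity(ras, labeling, reg.cell_type)
        p = empirical_pvalue(
            rm, reg.genes, labeling, reg.cell_type,
            n_boot=n_boot, seed=int(seeds[i] % (2**31)), top_fraction=top_fraction,
            rss_obs=rss,
        )
        scored.append(ScoredRegulon(reg, ras, rss, p))
    return call_ctsrs(scored, labeling, alpha)
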