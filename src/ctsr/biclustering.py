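"""Qualitative biclustering for gene-module detection.

The matrix is first reduced to a qualitative representation: per gene, the
top q-fraction of cells by expression become +1 (up), the bottom q-fraction
become −1 (down), the rest 0. Gene pairs sharing the same nonzero level in
many cells seed biclusters, which grow greedily by adding the gene that
keeps the most seed cells; a returned block is a constant-level submatrix.
The consistency parameter c bounds how many of the seed's cells an
expansion may shed (the block always retains ≥ c of the initial cells), so
c = 1 demands perfect blocks while c = 0.95 tolerates sporadic corruption.
All tie-breaks are deterministic (cell index, then lexicographic gene id).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse

from .types import Bicluster, ExpressionMatrix

log = logging.getLogger("ctsr")


@dataclass
class DiscreteMatrix:
    levels: np.ndarray  # genes x cells, int8 in {-1, 0, +1}
    gene_ids: list[str]
    cell_ids: list[str]
    q: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int8)
        if not np.isin(self.levels, (-1, 0, 1)).all():
            raise ValueError("levels must be in {-1, 0, +1}")


@dataclass
class BiclusterParams:
    q: float = 0.06
    consistency: float = 0.95
    max_biclusters: int = 500
    overlap_filter: float = 0.75
    levels: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if not 0 < self.q < 0.5:
            raise ValueError("q must be in (0, 0.5)")
        if not 0.5 < self.consistency <= 1:
            raise ValueError("consistency must be in (0.5, 1]")
        if self.max_biclusters < 1:
            raise ValueError("max_biclusters must be >= 1")
        if not 0 < self.overlap_filter <= 1:
            raise ValueError("overlap_filter must be in (0, 1]")


def discretize(em: ExpressionMatrix, q: float = 0.06) -> DiscreteMatrix:
    """Per-gene quantile discretization to {-1, 0, +1}.

    Zeros never become +1, constant genes stay all-zero, and ties at the
    quantile boundary are resolved by ascending cell index.
    """
    n = em.n_cells
    if n * q < 1:
        q_new = 1.0 / n
        log.warning("q=%g marks no cells for n=%d; raising q to %g", q, n, q_new)
        q = q_new
    k = math.ceil(q * n)
    values = em.values
    asc = np.argsort(values, axis=1, kind="stable")
    desc = np.argsort(-values, axis=1, kind="stable")
    levels = np.zeros(values.shape, dtype=np.int8)
    for g in range(em.n_genes):
        row = values[g]
        if row.max() == row.min():
            continue
        top = [i for i in desc[g, :k] if row[i] != 0]
        levels[g, top] = 1
        top_set = set(top)
        bottom = [i for i in asc[g, :k] if i not in top_set]
        levels[g, bottom] = -1
    return DiscreteMatrix(levels, list(em.gene_ids), list(em.cell_ids), q)


def seed_pairs(
    dm: DiscreteMatrix, levels: tuple[int, ...] = (1, -1)
) -> list[tuple[str, str, int]]:
    """Gene pairs ranked by shared-nonzero-level cell count (weight >= 2).

    Ties in weight are ordered by the lexicographic gene-id pair, and each
    pair is reported with its lexicographically smaller id first.
    """
    n_genes = len(dm.gene_ids)
    W = scipy.sparse.csr_matrix((n_genes, n_genes), dtype=np.int32)
    for level in levels:
        A = scipy.sparse.csr_matrix((dm.levels == level).astype(np.int32))
        W = W + A @ A.T
    W = scipy.sparse.triu(W, k=1).tocoo()
    mask = W.data >= 2
    rows, cols, weights = W.row[mask], W.col[mask], W.data[mask]
    if rows.size == 0:
        return []
    ids = np.asarray(dm.gene_ids, dtype=object)
    ida, idb = ids[rows], ids[cols]
    swap = ida > idb
    ida[swap], idb[swap] = idb[swap], ida[swap]
    order = np.lexsort((idb, ida, -weights))
    return [(ida[i], idb[i], int(weights[i])) for i in order]


def _expand(
    dm: DiscreteMatrix,
    gi: int,
    gj: int,
    consistency: float,
    allowed_levels: tuple[int, ...],
) -> Bicluster | None:
    lv = dm.levels
    best_level, best_cells = 0, None
    for level in allowed_levels:
        cells = np.flatnonzero((lv[gi] == level) & (lv[gj] == level))
        if best_cells is None or cells.size > best_cells.size or (
            cells.size == best_cells.size and level > best_level
        ):
            best_level, best_cells = level, cells
    if best_cells is None or best_cells.size < 2:
        return None
    level, cells = best_level, best_cells
    n0 = cells.size
    threshold = max(2, math.ceil(consistency * n0 - 1e-9))
    members = [gi, gj]
    member_set = {gi, gj}
    ids = dm.gene_ids
    while True:
        counts = (lv[:, cells] == level).sum(axis=1)
        counts[members] = -1
        best = int(counts.max())
        if best < threshold:
            break
        cand = np.flatnonzero(counts == best)
        g = min(cand, key=lambda i: ids[i])
        members.append(g)
        member_set.add(g)
        cells = cells[lv[g, cells] == level]
    return Bicluster(
        genes=[ids[g] for g in members],
        cells=[dm.cell_ids[c] for c in cells],
        level=int(level),
    )


def expand_seed(
    dm: DiscreteMatrix,
    pair: tuple[str, str],
    consistency: float = 0.95,
    levels: tuple[int, ...] = (1, -1),
) -> Bicluster | None:
    """Grow a bicluster from a seed gene pair at the given consistency."""
    idx = {g: i for i, g in enumerate(dm.gene_ids)}
    return _expand(dm, idx[pair[0]], idx[pair[1]], consistency, levels)


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def run_biclustering(
    em: ExpressionMatrix, params: BiclusterParams | None = None
) -> list[Bicluster]:
    """discretize → seed → expand, filtering near-duplicate gene sets.

    A candidate is kept only when its gene-set Jaccard overlap with every
    kept bicluster is below ``overlap_filter``; the search stops at
    ``max_biclusters`` kept blocks or seed exhaustion. Output is sorted by
    score (= genes × cells) descending.
    """
    params = params or BiclusterParams()
    dm = discretize(em, params.q)
    seeds = seed_pairs(dm, params.levels)
    idx = {g: i for i, g in enumerate(dm.gene_ids)}
    kept: list[Bicluster] = []
    kept_gene_sets: list[frozenset] = []
    for ga, gb, _w in seeds:
        if len(kept) >= params.max_biclusters:
            break
        bc = _expand(dm, idx[ga], idx[gb], params.consistency, params.levels)
        if bc is None:
            continue
        gene_set = frozenset(bc.genes)
        if any(_jaccard(gene_set, ks) >= params.overlap_filter for ks in kept_gene_sets):
            continue
        kept.append(bc)
        kept_gene_sets.append(gene_set)
    if not kept:
        log.warning("biclustering found no blocks")
    kept.sort(key=lambda b: (-b.score, tuple(b.genes)))
    return kept
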