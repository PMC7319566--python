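"""Cell-type assignment of biclusters by hypergeometric cell enrichment.

A bicluster becomes an "active gene module" of a cell type when its cell
set is enriched in that type's cells. Every (bicluster, cell type) pair is
tested; raw upper-tail p-values are Bonferroni-adjusted by the global
multiplier n_cell_types × n_biclusters, and pairs with adjusted p below
alpha are emitted. One bicluster can therefore seed modules in several
cell types; the best (smallest raw p) pair per bicluster is flagged.
"""
from __future__ import annotations

import logging

from scipy import stats

from .types import Bicluster, CellLabeling, GeneModule

log = logging.getLogger("ctsr")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) of Hypergeometric(N, K, n).

    ``k`` overlap, ``K`` cell-type size, ``n`` bicluster size, ``N`` total.
    """
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def assign_modules(
    biclusters: list[Bicluster],
    labeling: CellLabeling,
    alpha: float = 0.05,
) -> list[GeneModule]:
    """Emit a GeneModule for every (bicluster, cell type) pair with adj. p < alpha."""
    if not biclusters:
        return []
    label_map = labeling.as_dict()
    for bc in biclusters:
        missing = [c for c in bc.cells if c not in label_map]
        if missing:
            raise ValueError(f"bicluster cells missing from labeling: {missing[:5]}")
    N = len(labeling.cell_ids)
    type_cells = {
        ct: set(labeling.cells_of(ct)) for ct in labeling.label_set
    }
    multiplier = len(labeling.label_set) * len(biclusters)
    modules: list[GeneModule] = []
    for b_idx, bc in enumerate(biclusters):
        cells = set(bc.cells)
        best_p, best_at = None, None
        for ct in labeling.label_set:
            k = len(cells & type_cells[ct])
            p_raw = hypergeom_tail(k, len(type_cells[ct]), len(cells), N)
            if best_p is None or p_raw < best_p:
                best_p, best_at = p_raw, ct
            p_adj = min(1.0, p_raw * multiplier)
            if p_adj < alpha or alpha >= 1.0:
                modules.append(GeneModule(
                    genes=list(bc.genes), cell_type=ct,
                    p_raw=p_raw, p_adj=p_adj, source_bicluster=b_idx,
                ))
        for m in modules:
            if m.source_bicluster == b_idx and m.cell_type == best_at:
                m.best = True
    log.info(
        "module assignment: %d module(s) from %d bicluster(s) x %d cell type(s)",
        len(modules), len(biclusters), len(labeling.label_set),
    )
    return modules
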