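"""Rank matrices, RAS recovery curves, RSS divergence and CTSR calls."""
import math

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from ctsr import (
    CellLabeling,
    ExpressionMatrix,
    Regulon,
    call_ctsrs,
    empirical_pvalue,
    rank_genes_per_cell,
    regulon_activity,
    regulon_specificity,
)
from ctsr.scoring import RankMatrix, ScoredRegulon


def _em(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"c{i}" for i in range(values.shape[1])],
        normalized=True, log_transformed=True,
    )


def _rank_matrix(ranks_by_cell):
    """Build a RankMatrix from per-cell rank columns."""
    ranks = np.asarray(ranks_by_cell).T
    return RankMatrix(
        ranks,
        [f"g{i}" for i in range(ranks.shape[0])],
        [f"c{i}" for i in range(ranks.shape[1])],
    )


# ---------- ranking ----------

def test_rank_example():
    em = _em([[5], [9], [0]])
    rm = rank_genes_per_cell(em)
    assert rm.ranks[:, 0].tolist() == [2, 1, 3]


def test_all_tied_ranks_follow_gene_index():
    em = _em([[1], [1], [1]])
    rm = rank_genes_per_cell(em)
    assert rm.ranks[:, 0].tolist() == [1, 2, 3]


def test_rank_invariant_to_gene_order():
    vals = np.array([[5.0, 1], [9, 2], [3, 8], [0, 4]])
    em = rank_genes_per_cell(_em(vals))
    perm = [2, 0, 3, 1]
    em_p = rank_genes_per_cell(ExpressionMatrix(
        vals[perm], [f"g{i}" for i in perm], ["c0", "c1"], True, True
    ))
    for gi, g in enumerate([f"g{i}" for i in perm]):
        orig = int(g[1:])
        assert (em_p.ranks[gi] == em.ranks[orig]).all()


# ---------- RAS ----------

def _ras_oracle(ranks, regulon_rows, K):
    """Brute-force recovery-curve AUC for one cell."""
    counts = [sum(1 for r in regulon_rows if ranks[r] <= k) for k in range(1, K + 1)]
    g = len(regulon_rows)
    max_counts = [min(k, g) for k in range(1, K + 1)]
    return sum(counts) / sum(max_counts)


def test_ras_worked_example_six_ninths():
    # 10 genes, K=5, regulon at ranks {2, 4} -> RAS = 6/9
    ranks = [2, 4] + [r for r in range(1, 11) if r not in (2, 4)]
    rm = _rank_matrix([ranks])
    ras = regulon_activity(rm, ["g0", "g1"], top_fraction=0.5)
    assert ras[0] == pytest.approx(6 / 9)
    assert _ras_oracle(ranks, [0, 1], 5) == pytest.approx(6 / 9)


def test_ras_maximal_when_genes_on_top():
    ranks = list(range(1, 11))
    rm = _rank_matrix([ranks])
    assert regulon_activity(rm, ["g0", "g1", "g2"], 0.5)[0] == 1.0


def test_ras_zero_outside_top_k():
    ranks = list(range(1, 11))
    rm = _rank_matrix([ranks])
    assert regulon_activity(rm, ["g8", "g9"], 0.2)[0] == 0.0  # K=2, ranks 9 & 10


@pytest.mark.parametrize("seed", range(3))
def test_ras_matches_oracle_random(seed):
    rng = np.random.default_rng(seed)
    n = 40
    for _ in range(30):
        ranks = rng.permutation(n) + 1
        g = rng.integers(1, 10)
        rows = rng.choice(n, size=g, replace=False)
        K = math.ceil(0.2 * n)
        rm = _rank_matrix([ranks])
        ras = regulon_activity(rm, [f"g{r}" for r in rows], 0.2)
        assert ras[0] == pytest.approx(_ras_oracle(ranks, rows, K))


def test_ras_invariant_to_monotone_transform():
    rng = np.random.default_rng(1)
    vals = rng.random((30, 8))
    em1, em2 = _em(vals), _em(np.exp(3 * vals))  # strictly monotone transform
    genes = ["g2", "g5", "g11"]
    r1 = regulon_activity(rank_genes_per_cell(em1), genes)
    r2 = regulon_activity(rank_genes_per_cell(em2), genes)
    assert np.array_equal(r1, r2)


def test_ras_missing_genes():
    rm = _rank_matrix([[1, 2, 3]])
    with pytest.raises(ValueError):
        regulon_activity(rm, ["nope"])


# ---------- RSS ----------

def _labels4():
    return CellLabeling(["c0", "c1", "c2", "c3"], ["T", "T", "U", "U"])


def test_rss_matched_support_is_one():
    ras = np.array([0.5, 0.5, 0.0, 0.0])
    assert regulon_specificity(ras, _labels4(), "T") == pytest.approx(1.0)


def test_rss_disjoint_support_is_zero():
    ras = np.array([0.0, 0.0, 0.3, 0.7])
    assert regulon_specificity(ras, _labels4(), "T") == pytest.approx(0.0, abs=1e-12)


def test_rss_hand_example_matches_entropy_formula():
    ras = np.array([0.4, 0.1, 0.4, 0.1])
    labeling = CellLabeling(["c1", "c2", "c3", "c4"], ["T", "T", "U", "U"])
    p = ras / ras.sum()
    q = np.array([0.5, 0.5, 0.0, 0.0])
    m = (p + q) / 2

    def h(x):
        nz = x[x > 0]
        return -(nz * np.log2(nz)).sum()

    expected = 1 - math.sqrt(h(m) - (h(p) + h(q)) / 2)
    assert regulon_specificity(ras, labeling, "T") == pytest.approx(expected)
    # scipy's jensenshannon returns sqrt(JSD) directly — independent route
    assert regulon_specificity(ras, labeling, "T") == pytest.approx(
        1 - jensenshannon(p, q, base=2)
    )


def test_rss_bounded_on_random_inputs():
    rng = np.random.default_rng(2)
    cells = [f"c{i}" for i in range(20)]
    for _ in range(200):
        labs = CellLabeling(cells, ["A"] * 10 + ["B"] * 10)
        ras = rng.random(20) * rng.integers(1, 5)
        rss = regulon_specificity(ras, labs, "A")
        assert 0.0 <= rss <= 1.0


def test_rss_all_zero_ras_is_zero(caplog):
    with caplog.at_level("WARNING", logger="ctsr"):
        assert regulon_specificity(np.zeros(4), _labels4(), "T") == 0.0


# ---------- empirical p ----------

def _scoring_fixture(seed=0, n_genes=60, n_cells=40):
    rng = np.random.default_rng(seed)
    em = _em(rng.random((n_genes, n_cells)))
    labels = CellLabeling(em.cell_ids, ["A"] * (n_cells // 2) + ["B"] * (n_cells // 2))
    return em, labels


def test_empirical_p_floor():
    em, labels = _scoring_fixture()
    # plant a strongly A-specific regulon
    em.values[:5, :20] += 10.0
    rm = rank_genes_per_cell(em)
    p = empirical_pvalue(rm, [f"g{i}" for i in range(5)], labels, "A",
                         n_boot=100, seed=1)
    assert p == pytest.approx(1 / 101)


def test_empirical_p_errors():
    em, labels = _scoring_fixture()
    rm = rank_genes_per_cell(em)
    with pytest.raises(ValueError):
        empirical_pvalue(rm, ["g0"], labels, "A", n_boot=0, seed=0)
    with pytest.raises(ValueError):
        empirical_pvalue(rm, [], labels, "A", n_boot=10, seed=0)


# ---------- CTSR calls ----------

def _scored(cell_type, tf, rss, p, n_genes=6):
    reg = Regulon(cell_type, tf, "M", [f"g{i}" for i in range(n_genes)])
    return ScoredRegulon(reg, np.zeros(2), rss, p)


def _lab2():
    return CellLabeling(["c0", "c1"], ["CT1", "CT2"])


def test_bonferroni_within_cell_type():
    scored = [_scored("CT1", f"TF{i}", 0.5, 0.004) for i in range(5)]
    at05 = call_ctsrs([_scored("CT1", f"TF{i}", 0.5, 0.004) for i in range(5)],
                      _lab2(), alpha=0.05)
    assert np.allclose(at05.table.p_adjusted, 0.02)
    assert at05.table.is_ctsr.all()
    at01 = call_ctsrs(scored, _lab2(), alpha=0.01)
    assert not at01.table.is_ctsr.any()


def test_single_regulon_not_ctsr():
    out = call_ctsrs([_scored("CT1", "TF1", 0.4, 0.3)], _lab2(), alpha=0.05)
    assert out.table.p_adjusted.iloc[0] == pytest.approx(0.3)
    assert not out.table.is_ctsr.iloc[0]


def test_rank_tie_broken_by_rss():
    a = _scored("CT1", "TFa", 0.3, 0.01)
    b = _scored("CT1", "TFb", 0.8, 0.01)
    out = call_ctsrs([a, b], _lab2(), alpha=0.05)
    assert out.table[out.table.tf == "TFb"].name.iloc[0] == "CT1-R1"
    assert out.table[out.table.tf == "TFa"].name.iloc[0] == "CT1-R2"


def test_names_follow_label_order():
    regs = [_scored("CT2", "TFx", 0.5, 0.02), _scored("CT1", "TFy", 0.5, 0.02)]
    out = call_ctsrs(regs, _lab2(), alpha=0.05)
    assert out.table[out.table.cell_type == "CT1"].name.iloc[0] == "CT1-R1"
    assert out.table[out.table.cell_type == "CT2"].name.iloc[0] == "CT2-R1"
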