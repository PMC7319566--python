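"""Clustering fallback, agreement indexes and the one-vs-rest DEG test."""
import itertools

import numpy as np
import pytest
from sklearn import metrics as skm

from ctsr import (
    CellLabeling,
    ExpressionMatrix,
    cluster_cells,
    clustering_agreement,
    deg_coverage,
    find_degs,
)

from conftest import random_labeling


def _em(values, normalized=True):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"c{i}" for i in range(values.shape[1])],
        normalized=normalized, log_transformed=normalized,
    )


# ---------- cluster_cells ----------

def _blobs(seed=0, sep=10.0, n=50):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(30, n))
    b = rng.normal(sep, 1, size=(30, n))
    return _em(np.hstack([a, b])), ["A"] * n + ["B"] * n


def test_two_blobs_perfect_recovery():
    em, truth = _blobs()
    lab = cluster_cells(em, k=2, seed=0)
    truth_lab = CellLabeling(em.cell_ids, truth)
    assert clustering_agreement(lab, truth_lab).adjusted_rand == 1.0


def test_k1_single_label():
    em, _ = _blobs()
    lab = cluster_cells(em, k=1, seed=0)
    assert len(lab.label_set) == 1


def test_same_seed_identical():
    em, _ = _blobs()
    assert cluster_cells(em, k=2, seed=7).labels == cluster_cells(em, k=2, seed=7).labels


def test_too_few_cells_errors():
    em, _ = _blobs(n=2)
    with pytest.raises(ValueError):
        cluster_cells(em, k=10, seed=0)


# ---------- agreement indexes ----------

def _pair_oracle(a, b):
    """Brute-force pair enumeration of rand/jaccard/FM/ARI."""
    n = len(a)
    a11 = a10 = a01 = a00 = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            a11 += 1
        elif sa:
            a10 += 1
        elif sb:
            a01 += 1
        else:
            a00 += 1
    total = n * (n - 1) / 2
    return a11, a10, a01, a00, total


def test_identical_labelings_all_one():
    lab = CellLabeling(["c1", "c2", "c3"], ["x", "y", "x"])
    idx = clustering_agreement(lab, lab)
    assert idx.rand == idx.adjusted_rand == idx.jaccard == idx.fowlkes_mallows == 1.0


def test_label_name_invariance():
    a = CellLabeling(["c1", "c2", "c3", "c4"], ["1", "1", "2", "2"])
    b = CellLabeling(["c1", "c2", "c3", "c4"], ["B", "B", "A", "A"])
    idx = clustering_agreement(a, b)
    assert idx.rand == idx.adjusted_rand == idx.jaccard == idx.fowlkes_mallows == 1.0


def test_six_cell_example_matches_pair_enumeration():
    cells = [f"c{i}" for i in range(6)]
    la = ["1", "1", "1", "2", "2", "2"]
    lb = ["1", "1", "2", "2", "2", "2"]
    idx = clustering_agreement(CellLabeling(cells, la), CellLabeling(cells, lb))
    a11, a10, a01, a00, total = _pair_oracle(la, lb)
    assert idx.rand == pytest.approx((a11 + a00) / total)
    assert idx.jaccard == pytest.approx(a11 / (a11 + a10 + a01))
    assert idx.fowlkes_mallows == pytest.approx(
        a11 / np.sqrt((a11 + a10) * (a11 + a01))
    )
    # independent library cross-checks
    assert idx.rand == pytest.approx(skm.rand_score(la, lb))
    assert idx.adjusted_rand == pytest.approx(skm.adjusted_rand_score(la, lb))
    assert idx.fowlkes_mallows == pytest.approx(skm.fowlkes_mallows_score(la, lb))


def test_agreement_symmetry_random():
    rng = np.random.default_rng(3)
    cells = [f"c{i}" for i in range(40)]
    for _ in range(10):
        a = random_labeling(rng, cells, 3)
        b = random_labeling(rng, cells, 4)
        ab, ba = clustering_agreement(a, b), clustering_agreement(b, a)
        for f in ("rand", "adjusted_rand", "jaccard", "fowlkes_mallows"):
            assert getattr(ab, f) == pytest.approx(getattr(ba, f))


def test_ari_random_labelings_near_zero():
    rng = np.random.default_rng(4)
    cells = [f"c{i}" for i in range(200)]
    aris = []
    for _ in range(100):
        a = random_labeling(rng, cells, 4)
        b = random_labeling(rng, cells, 4)
        aris.append(clustering_agreement(a, b).adjusted_rand)
    assert abs(float(np.mean(aris))) < 0.02


def test_mismatched_cell_sets_error():
    a = CellLabeling(["c1", "c2"], ["x", "y"])
    b = CellLabeling(["c1", "c9"], ["x", "y"])
    with pytest.raises(ValueError):
        clustering_agreement(a, b)


# ---------- DEG detection ----------

def _rank_sum_exact_p(x, y):
    """Exact two-sided rank-sum tail by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    count = 0
    combos = list(itertools.combinations(range(n + m), n))
    for combo in combos:
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            count += 1
    return count / len(combos)


def test_identical_groups_p_one():
    values = np.vstack([np.ones(10), np.arange(10, dtype=float)])
    lab = CellLabeling([f"c{i}" for i in range(10)], ["A"] * 5 + ["B"] * 5)
    em = _em(values)
    df = find_degs(em, lab)
    flat = df[(df.gene_id == "g0") & (df.cell_type == "A")]
    assert flat.p_value.iloc[0] == pytest.approx(1.0)


def test_complete_separation_matches_exact_tail():
    x = np.array([6.0, 7, 8, 9, 10])
    y = np.array([1.0, 2, 3, 4, 5])
    values = np.vstack([np.concatenate([x, y])])
    lab = CellLabeling([f"c{i}" for i in range(10)], ["A"] * 5 + ["B"] * 5)
    df = find_degs(_em(values), lab)
    p = df[(df.gene_id == "g0") & (df.cell_type == "A")].p_value.iloc[0]
    assert p == pytest.approx(2 / 252)
    assert p == pytest.approx(_rank_sum_exact_p(x, y))


@pytest.mark.parametrize("n,m,seed", [(4, 5, 0), (6, 6, 1), (8, 7, 2)])
def test_small_tie_free_groups_match_enumeration(n, m, seed):
    rng = np.random.default_rng(seed)
    vals = rng.permutation(np.arange(1, n + m + 1)).astype(float)
    lab = CellLabeling([f"c{i}" for i in range(n + m)], ["A"] * n + ["B"] * m)
    df = find_degs(_em(np.vstack([vals])), lab)
    p = df[(df.gene_id == "g0") & (df.cell_type == "A")].p_value.iloc[0]
    assert p == pytest.approx(_rank_sum_exact_p(vals[:n], vals[n:]), rel=1e-9)


def test_null_calibration():
    rng = np.random.default_rng(5)
    values = rng.normal(size=(1000, 60))
    lab = CellLabeling([f"c{i}" for i in range(60)], ["A"] * 30 + ["B"] * 30)
    df = find_degs(_em(values), lab)
    frac = float((df[df.cell_type == "A"].p_value < 0.05).mean())
    se = np.sqrt(0.05 * 0.95 / 1000)
    assert abs(frac - 0.05) < 3 * se


def test_small_group_skipped(caplog):
    values = np.arange(12, dtype=float).reshape(2, 6)
    lab = CellLabeling([f"c{i}" for i in range(6)], ["A"] * 4 + ["B"] * 2)
    with caplog.at_level("WARNING", logger="ctsr"):
        df = find_degs(_em(values), lab)
    assert set(df.cell_type) == {"A"}


# ---------- DEG coverage ----------

def _deg_table(deg_genes, cell_type="CT1"):
    import pandas as pd
    return pd.DataFrame({
        "gene_id": deg_genes,
        "cell_type": cell_type,
        "log2_fold_change": 1.0,
        "p_value": 0.001,
        "adjusted_p": 0.01,
        "is_deg": True,
    })


def test_deg_coverage_limits():
    table = _deg_table(["g1", "g2"])
    assert deg_coverage(["g1", "g2"], table, "CT1") == 1.0
    assert deg_coverage(["g8", "g9"], table, "CT1") == 0.0
    with pytest.raises(ValueError):
        deg_coverage([], table, "CT1")


def test_deg_coverage_ratio_68_of_90():
    genes = [f"g{i}" for i in range(90)]
    table = _deg_table(genes[:68])
    assert deg_coverage(genes, table, "CT1") == pytest.approx(68 / 90)
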