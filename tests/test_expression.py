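"""Size factors, NB exact test, BH, clustering and qPCR fold changes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import _oracles
from palmirna.expression import (
    bh_adjust,
    complete_linkage_order,
    ddct_fold_change,
    de_table,
    drop_all_zero_rows,
    nb_exact_test,
    normalize,
    size_factors,
)


def _matrix(rng, rows=50, cols=4, lam=80):
    return pd.DataFrame(
        rng.poisson(lam, size=(rows, cols)) + 1,
        columns=[f"lib{i}" for i in range(cols)],
    )


def test_identical_libraries_have_unit_factors(rng):
    m = _matrix(rng)
    m["lib1"] = m["lib0"]
    model = size_factors(m[["lib0", "lib1"]])
    assert model.size_factors.to_numpy() == pytest.approx([1.0, 1.0])


def test_doubled_library_gives_sqrt2_factors(rng):
    a = rng.poisson(100, size=40) + 1
    m = pd.DataFrame({"A": a, "B": 2 * a})
    model = size_factors(m)
    assert model.size_factors.to_numpy() == pytest.approx(
        [1 / math.sqrt(2), math.sqrt(2)]
    )


def test_size_factors_match_direct_formula_coding(rng):
    for _ in range(30):
        m = pd.DataFrame(rng.integers(0, 200, size=(40, 4)))
        if not (m.to_numpy() > 0).all(axis=1).any():
            continue
        got = size_factors(m).size_factors.to_numpy()
        assert got == pytest.approx(_oracles.size_factors_direct(m.to_numpy()))


def test_size_factors_need_positive_row():
    m = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError):
        size_factors(m)


def test_scale_equivariance(rng):
    m = _matrix(rng, rows=30)
    base = size_factors(m).size_factors
    scaled = m.copy()
    scaled["lib2"] = scaled["lib2"] * 3
    got = size_factors(scaled).size_factors
    # scaling library 2 by 3 scales its factor by 3 relative to the others
    # (the common geometric-mean shift cancels in the ratio of ratios)
    assert got["lib2"] / base["lib2"] == pytest.approx(
        3 * (got["lib0"] / base["lib0"])
    )


def test_normalize_and_idempotence(rng):
    m = _matrix(rng)
    model = size_factors(m)
    n = normalize(m, model)
    assert n.iloc[3, 2] == pytest.approx(m.iloc[3, 2] / model.size_factors.iloc[2])
    refit = size_factors(n).size_factors.to_numpy()
    assert np.allclose(refit / refit[0], 1.0, atol=1e-9)


def test_nb_exact_symmetry_and_null():
    lfc, p = nb_exact_test(100, 100)
    assert lfc == 0.0 and p == pytest.approx(1.0)
    lfc_ab, p_ab = nb_exact_test(30, 90)
    lfc_ba, p_ba = nb_exact_test(90, 30)
    assert lfc_ab == pytest.approx(-lfc_ba)
    assert p_ab == pytest.approx(p_ba)


def test_nb_exact_matches_enumeration(rng):
    for _ in range(60):
        ya = int(rng.integers(0, 120))
        yb = int(rng.integers(0, 120))
        if ya + yb == 0 or ya + yb > 200:
            continue
        phi = float(rng.choice([0.0, 0.04, 0.2]))
        _, p = nb_exact_test(ya, yb, dispersion=phi)
        assert p == pytest.approx(_oracles.nb_exact_p_enumeration(ya, yb, phi), rel=1e-9)


def test_nb_exact_input_errors():
    with pytest.raises(ValueError):
        nb_exact_test(0, 0)
    with pytest.raises(ValueError):
        nb_exact_test(1, 2, dispersion=-0.1)


def test_bh_forced_example_and_oracle(rng):
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    for _ in range(30):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        assert bh_adjust(p) == pytest.approx(_oracles.bh_stepup(p))
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_de_table_significance_is_conjunction(rng):
    counts = pd.DataFrame(
        {
            "leaf_control": [100, 120, 90, 100, 2000],
            "leaf_nacl": [400, 118, 95, 104, 60],
        },
        index=[f"m{i}" for i in range(5)],
    )
    de = de_table(counts, [("leaf_control", "leaf_nacl")])
    assert set(de.columns) >= {"p_value", "fdr", "significant"}
    for _, row in de.iterrows():
        assert row.significant == (row.p_value < 0.05 and row.fdr < 0.05)
        assert row.dispersion == pytest.approx(0.04)


def test_all_zero_rows_removed():
    m = pd.DataFrame({"a": [0, 3], "b": [0, 4]})
    assert list(drop_all_zero_rows(m).index) == [1]


def test_identical_rows_merge_first():
    m = pd.DataFrame([[4, 4], [4, 4], [40, 2]], columns=["a", "b"])
    order, merges = complete_linkage_order(m)
    assert merges[0][:2] == (0, 1) and merges[0][2] == pytest.approx(0.0)


def test_clustering_matches_bruteforce_oracle(rng):
    m = pd.DataFrame(rng.integers(0, 300, size=(5, 4)).astype(float))
    order, merges = complete_linkage_order(m)
    pts = np.log2(m.to_numpy() + 1.0)
    assert merges == pytest.approx(_oracles.complete_linkage_bruteforce(pts))
    assert sorted(order) == list(range(5))


def test_clustering_matches_scipy_heights(rng):
    m = pd.DataFrame(rng.uniform(0, 500, size=(12, 4)))
    _, merges = complete_linkage_order(m)
    x = np.log2(m.to_numpy() + 1.0)
    z = hierarchy.linkage(x, method="complete")
    assert sorted(mm[2] for mm in merges) == pytest.approx(sorted(z[:, 2]))


def test_duplicated_rows_leave_topology_unchanged(rng):
    m = pd.DataFrame(rng.uniform(1, 400, size=(4, 3)))
    _, merges = complete_linkage_order(m)
    doubled = pd.concat([m, m], ignore_index=True)
    _, merges2 = complete_linkage_order(doubled)
    # the first merges join each row with its duplicate at distance 0
    assert all(mm[2] == pytest.approx(0.0) for mm in merges2[:4])
    heights = sorted(mm[2] for mm in merges)
    heights2 = sorted(mm[2] for mm in merges2)[4:]
    assert heights == pytest.approx(heights2)


def test_ddct_fold_changes():
    assert ddct_fold_change(20, 18, 22, 20) == pytest.approx(1.0)
    assert ddct_fold_change(19, 18, 22, 20) == pytest.approx(2.0)  # ddCt = -1
    assert ddct_fold_change(21.32, 18, 20, 20) == pytest.approx(2 ** -3.32)
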