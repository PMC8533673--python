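import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from divforest.splitcore import (
    SENTINEL,
    CandidateSet,
    NodeData,
    SamplingParams,
    Split,
    count_all_splits,
    draw_candidates,
    effective_nsplits,
    enumerate_thresholds,
    gini_decrease,
    select_best,
)

from conftest import brute_force_gini


def make_node(columns, labels):
    X = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    return NodeData(X, np.asarray(labels))


@pytest.mark.parametrize(
    "values, expected",
    [
        ([3, 1, 2, 2], [1.5, 2.5]),
        ([5, 5, 5], []),
        ([0.1, 0.2], [0.15]),
    ],
)
def test_enumerate_thresholds_midpoints(values, expected):
    np.testing.assert_allclose(enumerate_thresholds(np.array(values)), expected)


def test_enumerate_thresholds_strictly_increasing(rng):
    v = rng.normal(size=57)
    thr = enumerate_thresholds(v)
    assert thr.size == np.unique(v).size - 1
    assert (np.diff(thr) > 0).all()


@pytest.mark.parametrize(
    "columns, expected",
    [
        (([1, 2, 3], [7, 7, 7]), 2),
        (([4, 4, 4],), 0),
        (([1, 2, 3, 4], [5, 6, 7, 8], [0, 1, 2, 3]), 9),
    ],
)
def test_count_all_splits(columns, expected):
    node = make_node(columns, [0] * len(columns[0]))
    assert count_all_splits(node) == expected


@pytest.mark.parametrize(
    "nsplits, proptry, total, expected",
    [
        (30, 1.0, 100, 30),
        (30, 0.05, 19, 0),  # floor(0.95): the node becomes terminal
        (30, 1.0, 12, 12),
        (30, 0.05, 20, 1),
        (1, 1.0, 0, 0),
    ],
)
def test_effective_nsplits(nsplits, proptry, total, expected):
    assert effective_nsplits(SamplingParams(nsplits, proptry), total) == expected


@given(
    ns=st.integers(1, 300),
    pt_i=st.integers(1, 100),
    total=st.integers(0, 2000),
)
def test_effective_nsplits_monotone_and_proptry_one(ns, pt_i, total):
    pt = pt_i / 100.0
    base = effective_nsplits(SamplingParams(ns, pt), total)
    assert effective_nsplits(SamplingParams(ns + 1, pt), total) >= base
    assert effective_nsplits(SamplingParams(ns, min(1.0, pt + 0.01)), total) >= base
    assert effective_nsplits(SamplingParams(ns, pt), total + 1) >= base
    assert effective_nsplits(SamplingParams(ns, 1.0), total) == min(ns, total)


def test_gini_decrease_examples():
    node = make_node(([1, 2, 3, 4],), [1, 1, 0, 0])
    assert gini_decrease(Split(0, 2.5), node) == pytest.approx(0.5)
    # degenerate: threshold beyond the data leaves one child empty
    assert gini_decrease(Split(0, 9.0), node) == SENTINEL

    node8 = make_node((list(range(8)),), [1, 1, 0, 1, 1, 0, 0, 0])
    # left 3 rows (2 ones), right 5 rows (2 ones)
    assert gini_decrease(Split(0, 2.5), node8) == pytest.approx(1 / 30)


@given(st.data())
def test_gini_decrease_matches_brute_force(data):
    n = data.draw(st.integers(2, 30))
    vals = data.draw(
        st.lists(st.integers(0, 5), min_size=n, max_size=n).map(np.array)
    )
    labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    node = make_node((vals,), labels)
    thr_all = enumerate_thresholds(vals)
    for thr in thr_all:
        oracle = brute_force_gini(labels, vals <= thr)
        assert gini_decrease(Split(0, float(thr)), node) == pytest.approx(oracle)
        assert oracle >= -1e-12


def test_draw_candidates_counts_and_membership(rng):
    node = make_node(([1, 2, 3, 1, 2],), [0, 1, 0, 1, 0])
    # total = 2 splits; nsplits=5 with proptry=1 caps at 2 draws
    cand = draw_candidates(node, SamplingParams(5, 1.0), rng)
    assert len(cand) == 2
    assert set(np.round(cand.thresholds, 6)) <= {1.5, 2.5}
    # uncapped: a 6-distinct-value feature gives 5 thresholds >= 5 draws
    node2 = make_node(([1, 2, 3, 4, 5, 6],), [0, 1, 0, 1, 0, 1])
    cand2 = draw_candidates(node2, SamplingParams(5, 1.0), rng)
    assert len(cand2) == 5
    assert set(cand2.thresholds) <= {1.5, 2.5, 3.5, 4.5, 5.5}


def test_draw_candidates_empty_for_constant_node(rng):
    node = make_node(([7, 7, 7], [1, 1, 1]), [0, 1, 0])
    assert len(draw_candidates(node, SamplingParams(30, 1.0), rng)) == 0


def test_draw_candidates_uniform_over_split_problems(rng):
    # two equally rich features: each should receive ~half of 10,000 draws
    node = make_node((np.arange(101), np.arange(101)[::-1]), np.tile([0, 1], 101)[:101])
    cand = draw_candidates(node, SamplingParams(10_000, 1.0), rng)
    frac = (cand.features == 0).mean()
    assert 0.46 <= frac <= 0.54


def test_draw_candidates_redraws_constant_features(rng):
    node = make_node(([1, 2, 3, 4], [5, 5, 5, 5]), [0, 1, 0, 1])
    cand = draw_candidates(node, SamplingParams(3, 1.0), rng)
    assert len(cand) == 3
    assert (cand.features == 0).all()


def test_draw_candidates_bit_reproducible():
    node = make_node((np.arange(50) % 7, np.arange(50) % 5), np.arange(50) % 2)
    a = draw_candidates(node, SamplingParams(30, 1.0), np.random.default_rng(99))
    b = draw_candidates(node, SamplingParams(30, 1.0), np.random.default_rng(99))
    np.testing.assert_array_equal(a.features, b.features)
    np.testing.assert_array_equal(a.thresholds, b.thresholds)


def test_drawn_thresholds_always_separate(rng):
    for _ in range(20):
        X = rng.integers(0, 4, size=(15, 3)).astype(float)
        node = NodeData(X, rng.integers(0, 2, size=15))
        cand = draw_candidates(node, SamplingParams(20, 1.0), rng)
        for f, t in zip(cand.features, cand.thresholds):
            left = node.values[:, f] <= t
            assert left.any() and not left.all()


def test_select_best_picks_maximum(rng):
    node = make_node(([1, 2, 3, 4],), [1, 1, 0, 0])
    cand = CandidateSet(
        features=np.array([0, 0, 0]),
        thresholds=np.array([1.5, 2.5, 3.5]),
    )
    best = select_best(cand, node, rng)
    assert best.threshold == 2.5 and best.criterion == pytest.approx(0.5)


def test_select_best_empty_and_degenerate(rng):
    node = make_node(([1, 2],), [0, 1])
    assert select_best(CandidateSet(), node, rng) is None
    bad = CandidateSet(features=np.array([0]), thresholds=np.array([99.0]))
    assert select_best(bad, node, rng) is None


def test_select_best_breaks_ties_uniformly():
    # symmetric labels: thresholds 1.5 and 2.5 give identical criteria
    node = make_node(([1, 2, 3, 4],), [1, 0, 1, 0])
    wins = 0
    for s in range(2000):
        cand = CandidateSet(
            features=np.array([0, 0]), thresholds=np.array([1.5, 3.5])
        )
        best = select_best(cand, node, np.random.default_rng(s))
        wins += best.threshold == 1.5
    assert 0.45 <= wins / 2000 <= 0.55
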