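import numpy as np
import pytest

from divforest.pairsplits import (
    PAIR_SPLIT_TYPES,
    PairCaps,
    PairSplit,
    PairSplitProblem,
    draw_pair_splits,
    evaluate_pair_splits,
    interaction_scores,
    pair_node_candidates,
    route_pair_split,
    screen_pairs,
)
from divforest.splitcore import NodeData
from divforest.synthdata import SynthSpec, gen_xor


@pytest.fixture
def xor_node():
    ds = gen_xor(SynthSpec(n=200, p_signal=0, p_noise=0, xor_pairs=1, seed=21))
    return NodeData(ds.X, ds.y)


def test_seven_splits_share_bivariable_points(rng):
    X = rng.normal(size=(50, 3))
    node = NodeData(X, rng.integers(0, 2, size=50))
    for s in range(200):
        splits = draw_pair_splits(node, PairSplitProblem(0, 2),
                                  np.random.default_rng(s))
        assert len(splits) == 7
        assert sorted(sp.type for sp in splits) == sorted(PAIR_SPLIT_TYPES)
        biv = [sp for sp in splits if sp.type not in ("UNIV_J1", "UNIV_J2")]
        assert len({(sp.point1, sp.point2) for sp in biv}) == 1


def test_constant_member_degrades_to_univariable(rng):
    X = np.column_stack([np.arange(10.0), np.full(10, 1.0)])
    node = NodeData(X, np.arange(10) % 2)
    splits = draw_pair_splits(node, PairSplitProblem(0, 1), rng)
    assert len(splits) == 1 and splits[0].type == "UNIV_J1"
    X2 = np.column_stack([np.full(10, 1.0), np.full(10, 2.0)])
    node2 = NodeData(X2, np.arange(10) % 2)
    assert draw_pair_splits(node2, PairSplitProblem(0, 1), rng) == []


@pytest.mark.parametrize(
    "split_type, x, expect_left",
    [
        ("QUAL", (1.0, 1.0), True),
        ("QUAL", (-1.0, -1.0), True),
        ("QUAL", (-1.0, 1.0), False),
        ("QUANT_LL", (-1.0, 1.0), False),
        ("QUANT_LL", (-1.0, -1.0), True),
        ("QUANT_UU", (1.0, 1.0), True),
        ("QUANT_LU", (-1.0, 1.0), True),
        ("QUANT_UL", (1.0, -1.0), True),
        ("QUANT_UL", (-1.0, -1.0), False),
        ("UNIV_J1", (-1.0, 99.0), True),
        ("UNIV_J2", (99.0, -1.0), True),
    ],
)
def test_routing_geometry(split_type, x, expect_left):
    split = PairSplit(split_type, 0, 1, 0.0, 0.0)
    assert route_pair_split(split, np.array(x)) is expect_left


def test_routing_partitions_and_qual_is_corner_union(rng):
    pts = rng.normal(size=(1000, 2))
    for t in PAIR_SPLIT_TYPES:
        left = route_pair_split(PairSplit(t, 0, 1, 0.1, -0.2), pts)
        assert left.dtype == bool and left.shape == (1000,)  # two-way partition
    qual = route_pair_split(PairSplit("QUAL", 0, 1, 0.1, -0.2), pts)
    ll = route_pair_split(PairSplit("QUANT_LL", 0, 1, 0.1, -0.2), pts)
    uu = route_pair_split(PairSplit("QUANT_UU", 0, 1, 0.1, -0.2), pts)
    np.testing.assert_array_equal(qual, ll | uu)
    assert not (ll & uu).any()


def test_qual_split_solves_xor_where_univariable_fails(xor_node):
    qual = PairSplit("QUAL", 0, 1, 0.0, 0.0)
    crit = evaluate_pair_splits(xor_node, [qual])[0]
    assert crit >= 0.4
    # every univariable split on either member is nearly useless
    from divforest.selectors import rf_candidates
    from divforest.splitcore import evaluate_candidates

    cand = rf_candidates(xor_node, 2, np.random.default_rng(0))
    univ = evaluate_candidates(xor_node, cand.features, cand.thresholds)
    assert univ.max() <= 0.05


def test_screen_pairs_counts():
    rng = np.random.default_rng(2)
    X4 = rng.normal(size=(50, 4))
    y = rng.integers(0, 2, size=50)
    assert len(screen_pairs(X4, y)) == 6
    X150 = rng.normal(size=(60, 150))
    pairs = screen_pairs(X150, rng.integers(0, 2, size=60))
    assert len(pairs) == 5000
    assert all(p.j1 < p.j2 for p in pairs)


def test_screening_ranks_planted_pair_highly():
    """With one planted XOR pair among 120 noise features, the pair should
    score in the top 1% of all pairs in nearly every replicate."""
    hits = 0
    reps = 50
    for s in range(reps):
        ds = gen_xor(SynthSpec(n=400, p_signal=0, p_noise=120, xor_pairs=1, seed=s))
        score = interaction_scores(ds.X, ds.y)
        iu = np.triu_indices(ds.p, 1)
        vals = score[iu]
        rank = int((vals > score[0, 1]).sum())
        hits += rank < 0.01 * vals.size
    assert hits / reps >= 0.9


def test_pair_node_candidate_caps(rng):
    X = rng.normal(size=(100, 6))
    node = NodeData(X, rng.integers(0, 2, size=100))
    pairs = screen_pairs(X, node.y)
    assert len(pairs) == 15
    caps = PairCaps()
    for s in range(50):
        cand = pair_node_candidates(node, pairs, caps, np.random.default_rng(s))
        assert len(cand) == 70  # 10 problems x 7 splits, all features rich


def test_pair_node_candidates_with_constant_feature(rng):
    X = np.column_stack([np.arange(20.0), np.full(20, 3.0)])
    node = NodeData(X, np.arange(20) % 2)
    pairs = [PairSplitProblem(0, 1)]
    cand = pair_node_candidates(node, pairs, PairCaps(), rng)
    assert len(cand) == 1  # one eligible problem, univariable-only
    assert all(s.type == "UNIV_J1" for s in cand)


def test_candidate_count_matches_feasibility_oracle(rng):
    # mixed node: features 0,1 rich, feature 2 constant
    X = np.column_stack([rng.normal(size=30), rng.normal(size=30), np.zeros(30)])
    node = NodeData(X, rng.integers(0, 2, size=30))
    for s in range(30):
        r = np.random.default_rng(s)
        problems = [PairSplitProblem(0, 1), PairSplitProblem(0, 2),
                    PairSplitProblem(1, 2)]
        total = 0
        for pr in problems:
            got = draw_pair_splits(node, pr, r)
            both = node.thresholds(pr.j1).size > 0 and node.thresholds(pr.j2).size > 0
            one = (node.thresholds(pr.j1).size > 0) != (node.thresholds(pr.j2).size > 0)
            assert len(got) == (7 if both else (1 if one else 0))
            total += len(got)
        assert total == 7 + 1 + 1
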