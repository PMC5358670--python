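"""Structure search: split enumeration, beam behavior, both search regimes
against exhaustive oracles, and the counting contract."""

import itertools
import math
from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from brl.errors import ValidationError
from brl.search import (
    Beam,
    CandidateModel,
    count_matches,
    enumerate_binary_splits,
    enumerate_complete_split,
    expanded_tree,
    gss_search,
    lss_search,
    root_model,
    specialize_leaf,
    _parent_set_score,
    _singleton_model,
)

from conftest import make_discrete, random_discrete


# ---------------------------------------------------------------------------
# independent scoring oracle (exact rational K2 from full scans)


def k2_exact_from_counts(counts) -> Fraction:
    r, n = len(counts), sum(counts)
    val = Fraction(factorial(r - 1), factorial(n + r - 1))
    for c in counts:
        val *= factorial(int(c))
    return val


def tree_score_oracle(data, leaf_paths) -> float:
    """Score a tree given as a list of antecedent paths, via full scans."""
    total = Fraction(1)
    covered = 0
    for path in leaf_paths:
        counts = count_matches(data, path)
        covered += int(counts.sum())
        total *= k2_exact_from_counts(tuple(int(c) for c in counts))
    assert covered == data.m, "oracle tree does not partition the data"
    return math.log(total.numerator) - math.log(total.denominator)


# ---------------------------------------------------------------------------
# split enumeration


def test_binary_split_counts():
    assert enumerate_binary_splits(2) == [((0,), (1,))]
    three = enumerate_binary_splits(3)
    assert len(three) == 3
    assert set(frozenset(map(frozenset, p)) for p in three) == {
        frozenset({frozenset({0}), frozenset({1, 2})}),
        frozenset({frozenset({1}), frozenset({0, 2})}),
        frozenset({frozenset({2}), frozenset({0, 1})}),
    }
    assert len(enumerate_binary_splits(4)) == 7  # 2^(4-1) - 1
    assert enumerate_binary_splits(1) == []


def test_binary_splits_are_partitions_each_once():
    for arity in range(2, 6):
        seen = set()
        for part in enumerate_binary_splits(arity):
            assert len(part) == 2
            assert 0 in part[0]  # canonical: block with code 0 first
            union = sorted(part[0] + part[1])
            assert union == list(range(arity))
            key = frozenset(map(frozenset, part))
            assert key not in seen
            seen.add(key)
        assert len(seen) == 2 ** (arity - 1) - 1


def test_complete_split():
    assert enumerate_complete_split(3) == ((0,), (1,), (2,))
    assert enumerate_complete_split(4) == ((0,), (1,), (2,), (3,))
    # at arity 2 the complete split coincides with the unique binary split
    assert enumerate_complete_split(2) == tuple(enumerate_binary_splits(2)[0])
    with pytest.raises(ValidationError):
        enumerate_complete_split(1)


# ---------------------------------------------------------------------------
# beam


def test_beam_orders_dedups_and_evicts(fig3_dataset):
    beam = Beam(2)
    m0 = _singleton_model(fig3_dataset, 0)
    m1 = _singleton_model(fig3_dataset, 1)
    root = root_model(fig3_dataset)
    assert beam.push(m0)
    assert not beam.push(m0)  # structural duplicate
    beam.push(m1)
    beam.push(root)
    assert len(beam) == 2
    scores = [m.logscore for m in beam]
    assert scores == sorted(scores, reverse=True)
    assert beam.pop_best().logscore == max(m0.logscore, m1.logscore, root.logscore)
    with pytest.raises(ValidationError):
        Beam(0)


# ---------------------------------------------------------------------------
# specialize_leaf


def test_specialize_binary_variable_single_candidate(fig3_dataset):
    model = _singleton_model(fig3_dataset, 0)
    stats = {}
    cand = specialize_leaf(model, 0, 1, fig3_dataset, stats=stats)
    assert stats["specializations"] == 1  # binary: binary split == complete split
    # full-rescore oracle on the resulting tree
    paths = [leaf.path for leaf in cand.tree.leaves]
    assert cand.logscore == pytest.approx(
        tree_score_oracle(fig3_dataset, paths), abs=1e-9)


def test_specialize_three_valued_variable_four_candidates():
    rng = np.random.default_rng(0)
    data = make_discrete(rng.integers(0, 3, size=(30, 2)), [3, 3],
                         rng.integers(0, 2, 30) | np.r_[1, np.zeros(29, int)], 2)
    model = _singleton_model(data, 0)
    stats = {}
    cand = specialize_leaf(model, 0, 1, data, stats=stats)
    assert stats["specializations"] == 4  # 3 binary + 1 complete
    # returned model is the best across all four partitions (oracle-checked)
    leaf = model.tree.leaves[0]
    best = -math.inf
    partitions = [((0,), (1, 2)), ((1,), (0, 2)), ((2,), (0, 1)), ((0,), (1,), (2,))]
    for part in partitions:
        paths = [l.path for i, l in enumerate(model.tree.leaves) if i != 0]
        paths += [leaf.path + ((1, block),) for block in part]
        best = max(best, tree_score_oracle(data, paths))
    assert cand.logscore == pytest.approx(best, abs=1e-9)


def test_specialize_rejects_variable_on_path(fig3_dataset):
    model = _singleton_model(fig3_dataset, 0)
    with pytest.raises(ValidationError):
        specialize_leaf(model, 0, 0, fig3_dataset)


def test_specialize_returns_even_when_score_drops():
    # splitting on a class-independent variable: candidate still returned,
    # acceptance is the caller's decision
    rng = np.random.default_rng(3)
    codes = np.column_stack([rng.integers(0, 2, 40), rng.integers(0, 2, 40)])
    y = codes[:, 0].copy()
    data = make_discrete(codes, [2, 2], y, 2)
    model = _singleton_model(data, 0)
    cand = specialize_leaf(model, 0, 1, data)
    assert cand is not None
    assert cand.tree.n_leaves == 3


# ---------------------------------------------------------------------------
# LSS


def enumerate_depth2_scores(data):
    """Oracle: scores of every local tree of depth <= 2 over binary variables
    (root complete split, each leaf optionally complete-split by another var)."""
    scores = []
    for v in range(data.n):
        for choices in itertools.product([None, *range(data.n)], repeat=2):
            if v in choices:
                continue
            paths = []
            ok = True
            for code, w in zip((0, 1), choices):
                base = ((v, (code,)),)
                if w is None:
                    paths.append(base)
                else:
                    paths += [base + ((w, (0,)),), base + ((w, (1,)),)]
            scores.append(tree_score_oracle(data, paths))
    return scores


def test_lss_recovers_copied_predictor():
    rng = np.random.default_rng(1)
    codes = rng.integers(0, 2, size=(20, 6))
    y = codes[:, 0].copy()
    data = make_discrete(codes, [2] * 6, y, 2)
    model = lss_search(data)
    assert sorted(model.used_variables) == [0]
    assert model.tree.n_leaves == 2
    assert model.logscore == pytest.approx(max(enumerate_depth2_scores(data)), abs=1e-9)


def test_lss_xor_beats_every_depth1_model():
    rng = np.random.default_rng(2)
    codes = rng.integers(0, 2, size=(40, 5))
    y = codes[:, 0] ^ codes[:, 1]
    data = make_discrete(codes, [2] * 5, y, 2)
    model = lss_search(data)
    depth1 = [tree_score_oracle(data, [((v, (0,)),), ((v, (1,)),)])
              for v in range(5)]
    assert model.logscore >= max(depth1) - 1e-12
    assert set(model.used_variables) == {0, 1}


def test_lss_merges_redundant_context(fig3_dataset):
    """Identical class distributions under GeneA=1: the local tree keeps a
    single merged leaf there — 3 leaves against the global tree's 4."""
    model = lss_search(fig3_dataset)
    assert model.tree.n_leaves == 3
    merged = [l for l in model.tree.leaves if len(l.path) == 1]
    assert len(merged) == 1
    assert merged[0].path[0][0] == 0  # conditioned on GeneA only


def test_lss_single_predictor_returns_singleton():
    data = make_discrete([[0], [1], [0], [1]], [2], [0, 1, 0, 1], 2)
    model = lss_search(data)
    assert sorted(model.used_variables) == [0]


def test_lss_all_arity_one_returns_root():
    data = make_discrete([[0], [0], [0], [0]], [1], [0, 1, 0, 1], 2)
    model = lss_search(data)
    assert model.tree.n_leaves == 1
    assert model.used_variables == frozenset()


def test_search_validates_tree_invariants_each_model():
    rng = np.random.default_rng(5)
    for trial in range(5):
        data = random_discrete(rng, 25, 4, arity=3)
        for search in (lss_search, gss_search):
            model = search(data, max_conj=3, beam_width=8)
            model.tree.validate(data)  # partition, no-repeat, count agreement


def test_search_determinism():
    rng = np.random.default_rng(8)
    data = random_discrete(rng, 30, 5, arity=3)
    for search in (lss_search, gss_search):
        a = search(data)
        b = search(data)
        assert a.logscore == b.logscore
        assert a.tree.canonical_key() == b.tree.canonical_key()


def test_lss_gss_agree_when_best_is_depth1_binary():
    # single strongly informative binary predictor among binary noise:
    # global and local spaces coincide at depth 1
    rng = np.random.default_rng(13)
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    informative = y.copy()
    noise = rng.integers(0, 2, size=(60, 3))
    codes = np.column_stack([informative, noise])
    data = make_discrete(codes, [2] * 4, y, 2)
    l = lss_search(data)
    g = gss_search(data)
    assert sorted(l.used_variables) == sorted(g.used_variables) == [0]
    assert l.logscore == pytest.approx(g.logscore, abs=1e-12)


def test_lss_specialization_work_scales_quadratically_in_n():
    """Doubling n at fixed m, r and model capacity roughly quadruples (never
    much more than quadruples) the number of evaluated splits."""
    rng = np.random.default_rng(21)
    m = 60
    counts = {}
    for n in (12, 24, 48):
        codes = rng.integers(0, 3, size=(m, n))
        y = (codes[:, 0] > 0).astype(int) ^ (rng.random(m) < 0.05).astype(int)
        data = make_discrete(codes, [3] * n, y, 2)
        stats = {}
        lss_search(data, max_conj=3, stats=stats)
        counts[n] = stats["specializations"]
    assert counts[24] / counts[12] <= 4.6
    assert counts[48] / counts[24] <= 4.6


# ---------------------------------------------------------------------------
# GSS


def test_gss_fully_expanded_leaf_counts():
    rng = np.random.default_rng(3)
    data = make_discrete(
        np.column_stack([rng.integers(0, 3, 30), rng.integers(0, 4, 30)]),
        [3, 4], rng.permutation([0, 1] * 15), 2)
    tree = expanded_tree(data, [0, 1])
    assert tree.n_leaves == 12  # 3 * 4


def test_gss_matches_exhaustive_parent_set_oracle():
    rng = np.random.default_rng(17)
    trials = 0
    for _ in range(60):
        n = int(rng.integers(2, 5))
        m = int(rng.integers(4, 9))
        data = random_discrete(rng, m, n)
        trials += 1
        oracle = max(
            _parent_set_score(data, set(s))[0]
            for k in range(1, n + 1)
            for s in itertools.combinations(range(n), k))
        got = gss_search(data, max_conj=n, beam_width=1000)
        assert got.logscore == pytest.approx(oracle, abs=1e-9)
    assert trials >= 40


def test_gss_respects_max_conj():
    rng = np.random.default_rng(19)
    data = random_discrete(rng, 40, 6)
    model = gss_search(data, max_conj=2)
    assert len(model.used_variables) <= 2


def test_expanded_tree_score_counts_empty_cells_as_unit():
    # sparse joint space: occupied-cell scoring equals the full product
    rng = np.random.default_rng(23)
    data = random_discrete(rng, 10, 3, arity=4)
    tree = expanded_tree(data, [0, 1, 2])
    score, n_leaves = _parent_set_score(data, [0, 1, 2])
    assert n_leaves == 64
    assert tree.logscore() == pytest.approx(score, abs=1e-9)


# ---------------------------------------------------------------------------
# count_matches


def test_count_matches_contract():
    rng = np.random.default_rng(29)
    data = random_discrete(rng, 50, 4, arity=3)
    marg = count_matches(data, [])
    assert marg.tolist() == np.bincount(data.target_codes, minlength=2).tolist()
    assert count_matches(data, [(0, ())]).tolist() == [0, 0]
    for _ in range(20):
        k = rng.integers(1, 4)
        antecedent = [
            (int(v), tuple(sorted(rng.choice(3, size=rng.integers(1, 3),
                                             replace=False))))
            for v in rng.choice(4, size=k, replace=False)]
        naive = np.zeros(2, dtype=int)
        for s in range(data.m):
            if all(data.codes[s, v] in blk for v, blk in antecedent):
                naive[data.target_codes[s]] += 1
        assert count_matches(data, antecedent).tolist() == naive.tolist()
    with pytest.raises(ValidationError):
        count_matches(data, [(99, (0,))])
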