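import itertools

import numpy as np
import pytest

from cryptclock._tree import parse_newick
from cryptclock.markers import NA, CharacterMatrix
from cryptclock.parsimony_phylo import (
    NORMAL_TIP,
    assign_branch_lengths,
    build_distance_table,
    distance_from_normal,
    diversity,
    fitch_score,
    patristic_distance,
    search_parsimony,
)
from cryptclock.profiles_io import ValidationError


def matrix_from_rows(rows: dict[str, list[int]]) -> CharacterMatrix:
    ids = list(rows)
    values = np.array([rows[s] for s in ids], dtype=np.int8)
    markers = [f"m{i}" for i in range(values.shape[1])]
    return CharacterMatrix(ids, markers, values)


def sankoff_score(tree, matrix) -> int:
    """Independent oracle: unit-cost Sankoff dynamic programming."""
    costs = {}
    total = 0
    by_id = {s: i for i, s in enumerate(matrix.sample_ids)}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label == NORMAL_TIP:
                obs = [0] * matrix.shape[1]
            else:
                obs = matrix.values[by_id[node.label]]
            c = np.zeros((matrix.shape[1], 2))
            for j, v in enumerate(obs):
                if v == NA:
                    continue
                c[j, 1 - v] = np.inf
            costs[node] = c
        else:
            acc = np.zeros((matrix.shape[1], 2))
            for child in node.children:
                cc = costs[child]
                # min over child state of (child cost + unit change cost)
                stay = cc
                switch = cc[:, ::-1] + 1
                acc = acc + np.minimum(stay, switch)
            costs[node] = acc
    return int(costs[tree.root].min(axis=1).sum())


class TestFitchScore:
    def test_identical_tips_zero(self):
        tree = parse_newick("((a,b),(c,d));")
        m = matrix_from_rows({s: [1, 1] for s in "abcd"})
        assert fitch_score(tree, m) == 0

    def test_single_origin_one_change(self):
        tree = parse_newick("((a,b),(c,d));")
        m = matrix_from_rows({"a": [0], "b": [0], "c": [1], "d": [1]})
        assert fitch_score(tree, m) == 1

    def test_incompatible_pattern_two_changes(self):
        tree = parse_newick("((a,b),(c,d));")
        m = matrix_from_rows({"a": [0], "b": [1], "c": [0], "d": [1]})
        assert fitch_score(tree, m) == 2

    def test_unknown_tip_rejected(self):
        tree = parse_newick("((a,b),(c,x));")
        m = matrix_from_rows({s: [0] for s in "abcd"})
        with pytest.raises(ValidationError):
            fitch_score(tree, m)

    def test_matches_sankoff_on_random_instances(self):
        rng = np.random.default_rng(7)
        newicks = [
            "((a,b),(c,d));",
            "(((a,b),c),(d,e));",
            "((a,(b,c)),((d,e),f));",
            "(normal,((a,b),(c,d)));",
        ]
        for nwk in newicks:
            tree = parse_newick(nwk)
            tips = [t for t in tree.tip_labels() if t != NORMAL_TIP]
            for _ in range(20):
                values = rng.integers(0, 2, size=(len(tips), 6)).astype(np.int8)
                mask = rng.random(values.shape) < 0.1
                mask[0] = False  # keep every column informative somewhere
                values[mask] = NA
                m = CharacterMatrix(tips, [f"m{i}" for i in range(6)], values)
                assert fitch_score(tree, m) == sankoff_score(tree, m)


class TestSearch:
    def test_three_samples_single_topology(self):
        m = matrix_from_rows({"a": [1, 0], "b": [1, 1], "c": [0, 0]})
        best, co_optimal, score = search_parsimony(m, mode="exhaustive")
        assert NORMAL_TIP in best.tip_labels()
        assert score == fitch_score(best, m)

    def test_exhaustive_limit(self):
        rows = {f"s{i}": [i % 2] for i in range(10)}
        with pytest.raises(ValidationError, match="exhaustive"):
            search_parsimony(matrix_from_rows(rows), mode="exhaustive")

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            search_parsimony(matrix_from_rows({"a": [1], "b": [0]}))

    def test_recovers_known_tree_unique_events(self):
        # clade events: (ab), (abc), (de) + tip-private markers
        rows = {
            "a": [1, 1, 0, 1, 0, 0, 0, 0],
            "b": [1, 1, 0, 0, 1, 0, 0, 0],
            "c": [0, 1, 0, 0, 0, 1, 0, 0],
            "d": [0, 0, 1, 0, 0, 0, 1, 0],
            "e": [0, 0, 1, 0, 0, 0, 0, 1],
        }
        m = matrix_from_rows(rows)
        best, co, score = search_parsimony(m, mode="exhaustive")
        assert score == 8  # one origin per character
        newick = best.newick()
        canon = {frozenset(x) for x in [("a", "b"), ("a", "b", "c"), ("d", "e")]}

        def clades(tree):
            out = set()
            below = {}
            for node in tree.postorder():
                below[node] = (frozenset([node.label]) if node.is_leaf
                               else frozenset().union(*(below[c] for c in node.children)))
                if not node.is_leaf and NORMAL_TIP not in below[node]:
                    out.add(below[node])
            return out

        assert canon <= clades(best)

    def test_heuristic_matches_exhaustive(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = int(rng.integers(4, 7))
            values = rng.integers(0, 2, size=(n, 8)).astype(np.int8)
            m = CharacterMatrix([f"s{i}" for i in range(n)],
                                [f"m{i}" for i in range(8)], values)
            _, _, s_ex = search_parsimony(m, mode="exhaustive")
            _, _, s_h = search_parsimony(m, mode="heuristic", n_restarts=10,
                                         seed=trial)
            assert s_h == s_ex

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 2, size=(6, 10)).astype(np.int8)
        m = CharacterMatrix([f"s{i}" for i in range(6)],
                            [f"m{i}" for i in range(10)], values)
        t1, _, _ = search_parsimony(m, seed=5)
        t2, _, _ = search_parsimony(m, seed=5)
        assert t1.newick() == t2.newick()


class TestBranchLengths:
    def test_zero_score_all_zero(self):
        tree = parse_newick("((a,b),(c,d));")
        m = matrix_from_rows({s: [1] for s in "abcd"})
        assign_branch_lengths(tree, m)
        assert sum(n.length or 0 for n in tree.postorder()) == 0

    def test_single_origin_single_branch(self):
        tree = parse_newick("((a,b),(c,d));")
        m = matrix_from_rows({"a": [0], "b": [0], "c": [1], "d": [1]})
        assign_branch_lengths(tree, m)
        lengths = [n.length for n in tree.postorder() if n is not tree.root]
        assert sorted(lengths) == [0, 0, 0, 0, 0, 1]

    def test_total_equals_fitch_score_random(self):
        rng = np.random.default_rng(13)
        newicks = ["((a,b),(c,d));", "(((a,b),c),(d,e));",
                   "(normal,((a,(b,c)),(d,e)));"]
        for nwk in newicks:
            for trial in range(20):
                tree = parse_newick(nwk)
                tips = [t for t in tree.tip_labels() if t != NORMAL_TIP]
                values = rng.integers(0, 2, size=(len(tips), 7)).astype(np.int8)
                m = CharacterMatrix(tips, [f"m{i}" for i in range(7)], values)
                score = fitch_score(tree, m)
                assign_branch_lengths(tree, m)
                total = sum(n.length for n in tree.postorder()
                            if n is not tree.root)
                assert total == score


class TestDistances:
    def test_self_distance_zero(self):
        tree = parse_newick("((a:2,b:3):1,c:4);")
        assert patristic_distance(tree, "a", "a") == 0.0

    def test_sibling_distance(self):
        tree = parse_newick("((a:2,b:3):1,c:4);")
        assert patristic_distance(tree, "a", "b") == 5.0

    def test_unknown_tip_rejected(self):
        tree = parse_newick("((a:2,b:3):1,c:4);")
        with pytest.raises(KeyError):
            patristic_distance(tree, "a", "zz")

    def test_matches_brute_force_path_sum(self):
        rng = np.random.default_rng(17)
        tree = parse_newick("(((a,b),(c,d)),((e,f),g));")
        for node in tree.postorder():
            if node is not tree.root:
                node.length = float(rng.integers(0, 10))
        depths = tree.depths()

        def brute(x, y):
            # via shared-ancestor depth
            ax = tree.find(x)
            ancestors = set()
            n = ax
            while n is not None:
                ancestors.add(id(n))
                n = n.parent
            n = tree.find(y)
            while id(n) not in ancestors:
                n = n.parent
            return depths[ax] + depths[tree.find(y)] - 2 * depths[n]

        for x, y in itertools.combinations("abcdefg", 2):
            assert patristic_distance(tree, x, y) == pytest.approx(brute(x, y))

    def test_distance_from_normal(self):
        tree = parse_newick("(normal:0,(a:2,b:3):4);")
        assert distance_from_normal(tree, "a") == 6.0


class TestDiversity:
    def test_two_tips(self):
        tree = parse_newick("((a:2,b:2):0,c:9);")
        assert diversity(tree, ["a", "b"]) == 4.0

    def test_identical_tips_zero(self):
        tree = parse_newick("((a:0,b:0):1,c:2);")
        assert diversity(tree, ["a", "b"]) == 0.0

    def test_singleton_rejected(self):
        tree = parse_newick("(a:1,b:1);")
        with pytest.raises(ValidationError):
            diversity(tree, ["a"])

    def test_four_tip_hand_mean(self):
        tree = parse_newick("((a:1,b:2):1,(c:3,d:4):2);")
        # pairwise: ab=3, ac=7, ad=8, bc=8, bd=9, cd=7 -> mean 42/6
        assert diversity(tree, "abcd") == pytest.approx(7.0)


def test_distance_table_covariates(crypt_meta_factory):
    tree = parse_newick("((a:1,b:2):1,c:5);")
    metas = [
        crypt_meta_factory("a", "B1", section=1),
        crypt_meta_factory("b", "B1", section=4),
        crypt_meta_factory("c", "B2", section=1),
    ]
    table = build_distance_table(tree, metas)
    row_ab = table[(table.sample1 == "a") & (table.sample2 == "b")].iloc[0]
    assert row_ab.same_biopsy and row_ab.physical_distance == 3
    row_ac = table[(table.sample1 == "a") & (table.sample2 == "c")].iloc[0]
    assert not row_ac.same_biopsy
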