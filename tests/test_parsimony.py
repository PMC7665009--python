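import random
import re

import pytest

from ontochron import (
    SearchOptions,
    acctran_changes,
    branch_and_bound_search,
    char_max_steps,
    char_min_steps,
    condense_and_dedupe,
    fitch_length,
    fit_statistics,
    from_newick,
    heuristic_search,
)
from ontochron.parsimony import ParsimonyError, truncate2
from ontochron.tree import ANCESTOR_LABEL, Node, Tree

import _oracles as oracle
from conftest import make_matrix, random_rows


def rooted(newick: str) -> Tree:
    """Attach the all-absent ancestor root above a Newick subtree."""
    t = from_newick(newick)
    root = Node(ANCESTOR_LABEL)
    root.add(t.root)
    return Tree(root)


def labelled_matrix(rows: dict[str, str]):
    from ontochron import CharacterMatrix, OTULabel
    from ontochron.matrix_io import default_characters

    otus = tuple(OTULabel(name, float(i)) for i, name in enumerate(rows))
    return CharacterMatrix(
        otus=otus,
        characters=default_characters(len(next(iter(rows.values())))),
        rows=tuple(rows.values()),
    )


def tree_over(m, newick=None):
    """A tree whose leaves carry the matrix's own labels; ``newick`` may
    use the bare species names, which are rewritten to full OTU labels."""
    if newick is None:
        newick = "(" + ",".join(f"'{o.label}'" for o in m.otus) + ");"
    else:
        for o in m.otus:
            newick = re.sub(rf"\b{re.escape(o.species)}\b", f"'{o.label}'", newick)
    return rooted(newick)


class TestFitchLength:
    def test_single_origin_costs_one(self):
        m = labelled_matrix({"A": "0", "B": "0", "C": "1", "D": "1"})
        t = tree_over(m, "((A,B),(C,D));")
        assert fitch_length(t, m) == 1

    def test_all_unknown_character_costs_nothing(self):
        m = labelled_matrix({"A": "?", "B": "?", "C": "?"})
        assert fitch_length(tree_over(m), m) == 0

    def test_label_mismatch_rejected(self):
        m = labelled_matrix({"A": "1", "B": "0"})
        t = rooted("(A,X);")
        with pytest.raises(ParsimonyError):
            fitch_length(t, m)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_random_binary_trees(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 9)
        k = rng.randint(2, 8)
        rows = random_rows(rng, n, k, missing=0.15, distinct=False,
                           allow_zero=True)
        topo = 0 if n == 1 else (0, 1)
        for x in range(2, n):
            topo = rng.choice(list(oracle.insert_everywhere(topo, x)))
        want = oracle.tree_length(topo, rows)

        m = make_matrix(rows)

        def build(t):
            if not isinstance(t, tuple):
                return Node(m.otus[t].label)
            return Node(None, [build(t[0]), build(t[1])])

        root = Node(ANCESTOR_LABEL)
        root.add(build(topo))
        assert fitch_length(Tree(root), m) == want

    def test_polytomies_scored_exactly(self):
        m = labelled_matrix({"A": "1", "B": "1", "C": "1", "D": "0"})
        # every leaf directly under the all-zero root: each 1 is a step
        true_star = Tree(Node(ANCESTOR_LABEL,
                              [Node(o.label) for o in m.otus]))
        assert fitch_length(true_star, m) == 3
        # one free node above the root absorbs the shared gain
        bush = tree_over(m)  # ancestor -> (A,B,C,D)
        assert fitch_length(bush, m) == 2
        # fully resolved: single gain below D's split
        resolved = tree_over(m, "(((A,B),C),D);")
        assert fitch_length(resolved, m) == 1


class TestStepBounds:
    @pytest.mark.parametrize(
        "column,lo,hi",
        [
            ("0000" + "1" * 16, 1, 4),
            ("00000", 0, 0),
            ("01??", 1, 1),
            ("??", 0, 0),
        ],
    )
    def test_examples(self, column, lo, hi):
        assert char_min_steps(column) == lo
        assert char_max_steps(column) == hi


class TestSearchAgainstEnumeration:
    @pytest.mark.parametrize("seed", range(8))
    def test_exact_search_equals_exhaustive(self, seed):
        rng = random.Random(100 + seed)
        n = rng.randint(4, 7)
        k = rng.randint(3, 8)
        rows = random_rows(rng, n, k)
        want_len, want_trees = oracle.exhaustive_mp(rows)
        want_set = {oracle.topo_canonical(t) for t in want_trees}

        m = make_matrix(rows)
        res = branch_and_bound_search(m, SearchOptions(collapse_rule="none"))
        assert res.best_length == want_len

        label_to_id = {o.label: i for i, o in enumerate(m.otus)}

        def canon(node):
            if node.is_leaf:
                return label_to_id[node.label]
            return frozenset(canon(c) for c in node.children)

        got = set()
        for t in res.trees:
            (top,) = t.root.children  # no all-zero rows: root has one child
            got.add(canon(top))
        assert got == want_set

    @pytest.mark.parametrize("seed", range(4))
    def test_heuristic_never_beats_exact_and_is_deterministic(self, seed):
        rng = random.Random(200 + seed)
        rows = random_rows(rng, 6, 6)
        m = make_matrix(rows)
        exact = branch_and_bound_search(m).best_length
        opts = SearchOptions(mode="heuristic", seed=seed)
        h1 = heuristic_search(m, opts)
        h2 = heuristic_search(m, opts)
        assert h1.best_length >= exact
        assert h1.best_length == h2.best_length
        assert [t.canonical() for t in h1.trees] == [t.canonical() for t in h2.trees]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ParsimonyError):
            branch_and_bound_search(make_matrix(["01"]))


class TestSearchProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_and_invariances(self, seed):
        rng = random.Random(300 + seed)
        rows = random_rows(rng, 6, 7)
        m = make_matrix(rows)
        res = branch_and_bound_search(m)
        fit = res.fit
        assert fit.M <= res.best_length <= fit.G

        # removing a character never increases the best length
        drop = rng.randrange(m.n_characters)
        fewer_rows = [r[:drop] + r[drop + 1:] for r in rows]
        distinct = {r for r in fewer_rows if set(r) & {"1"}}
        if len(distinct) >= 2:
            fewer = make_matrix(fewer_rows)
            assert branch_and_bound_search(fewer).best_length <= res.best_length

        # duplicating a row never changes the best length
        dup = make_matrix(list(rows) + [rows[0]])
        assert branch_and_bound_search(dup).best_length == res.best_length

    def test_max_trees_cap_is_flagged(self):
        rows = ["01?", "10?", "011", "101", "110"]
        m = make_matrix(rows)
        res = branch_and_bound_search(
            m, SearchOptions(collapse_rule="none", max_trees=1)
        )
        full = branch_and_bound_search(m, SearchOptions(collapse_rule="none"))
        if full.n_trees > 1:
            assert res.capped


class TestCondense:
    def test_identical_leaves_collapse_to_root_polytomy(self):
        # four all-zero leaves + one derived: every internal branch among
        # the zeros has maximum length zero and vanishes
        m = labelled_matrix(
            {"A": "00", "B": "00", "C": "00", "D": "00", "E": "11"}
        )
        t = tree_over(m, "((((A,B),C),D),E);")
        (condensed,) = condense_and_dedupe([t], m, "min-zero")
        assert len(condensed.root.children) == 5
        assert all(c.is_leaf for c in condensed.root.children)

    def test_duplicates_after_collapse_merge(self):
        m = labelled_matrix({"A": "10", "B": "10", "C": "01"})
        t1 = tree_over(m, "((A,B),C);")
        t2 = tree_over(m, "((B,A),C);")
        assert len(condense_and_dedupe([t1, t2], m, "none")) == 1

    def test_min_zero_collapses_at_least_as_much_as_max_zero(self, frame_5_10_20):
        res = branch_and_bound_search(
            frame_5_10_20, SearchOptions(collapse_rule="none")
        )
        n_min = len(condense_and_dedupe(res.trees, frame_5_10_20, "min-zero"))
        n_max = len(condense_and_dedupe(res.trees, frame_5_10_20, "max-zero"))
        assert n_min <= n_max <= res.n_trees


class TestAcctran:
    def test_single_origin_maps_to_subtending_branch(self):
        m = labelled_matrix({"A": "0", "B": "0", "C": "1", "D": "1"})
        t = tree_over(m, "((A,B),(C,D));")
        changes = acctran_changes(t, m)
        by_node = {id(n): n for n in t.preorder()}
        (node_id,) = changes
        node = by_node[node_id]
        assert {leaf.label.split("_")[0] for leaf in node.leaves()} == {"C", "D"}
        assert [(c.char_index, c.kind) for c in changes[node_id]] == [(1, "gain")]

    def test_ambiguity_resolved_as_early_gain_plus_reversal(self):
        # 0,1,1,1 on ((A,B),(C,D)): both "two parallel gains" and "deep
        # gain plus reversal in A" are optimal; ACCTRAN takes the latter
        m = labelled_matrix({"A": "0", "B": "1", "C": "1", "D": "1"})
        t = tree_over(m, "((A,B),(C,D));")
        changes = acctran_changes(t, m)
        kinds = sorted(
            c.kind for chs in changes.values() for c in chs
        )
        assert kinds == ["gain", "loss"]
        # the reversal sits on A's terminal branch
        by_node = {id(n): n for n in t.preorder()}
        losses = [
            by_node[nid]
            for nid, chs in changes.items()
            for c in chs
            if c.kind == "loss"
        ]
        assert [n.label.split("_")[0] for n in losses] == ["A"]

    @pytest.mark.parametrize("seed", range(6))
    def test_total_changes_equal_tree_length_and_respect_bounds(self, seed):
        rng = random.Random(400 + seed)
        n = rng.randint(4, 8)
        rows = random_rows(rng, n, 6, missing=0.15, distinct=False,
                           allow_zero=True)
        m = make_matrix(rows)
        res = branch_and_bound_search(m, SearchOptions(collapse_rule="none"))
        t = res.trees[0]
        changes = acctran_changes(t, m)
        per_char: dict[int, int] = {}
        for chs in changes.values():
            for c in chs:
                per_char[c.char_index] = per_char.get(c.char_index, 0) + 1
        assert sum(per_char.values()) == fitch_length(t, m) == res.best_length
        for j in range(1, m.n_characters + 1):
            col = m.column(j) + "0"  # the all-zero ancestor is part of the tree
            assert char_min_steps(col) <= per_char.get(j, 0) <= max(
                char_max_steps(col), char_min_steps(col)
            )


class TestFitStatistics:
    def test_truncation_is_not_rounding(self):
        assert truncate2(53 / 62) == 0.85
        assert truncate2(53 / 71) == 0.74  # rounding would print 0.75

    def test_ci_is_one_without_homoplasy(self):
        m = labelled_matrix({"A": "100", "B": "110", "C": "111"})
        res = branch_and_bound_search(m)
        assert res.fit.ci == 1.0

    def test_all_constant_matrix_rejected(self):
        m = labelled_matrix({"A": "11", "B": "11"})
        with pytest.raises(ParsimonyError):
            fit_statistics(1, m)
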