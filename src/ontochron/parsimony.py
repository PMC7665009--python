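"""Maximum-parsimony search and character-fit statistics.

The analysis substrate is a binary presence/absence matrix whose rows are
species x time-landmark OTUs. Trees are rooted by a hypothetical all-absent
ancestor (development starts with no organs), so the 0%-of-development OTUs
sit at the root. Characters are unweighted and unordered; ``?`` cells are
treated as the full state set {0, 1} during optimization. Organ loss is
allowed and appears as character reversal.

Search strategy
---------------
Identical matrix rows are merged into one search taxon and re-expanded
afterwards: the four all-zero 0% rows coincide with the hypothetical
ancestor and become its children. Exact search enumerates tree topologies
by stepwise insertion with branch-and-bound pruning (Fitch length is
monotone under leaf addition); the initial upper bound comes from the
heuristic search. Equally parsimonious trees are condensed (zero-length
branches collapsed) and deduplicated before they are counted.

State sets are packed into per-row bit masks (one bit per character for
each of the two states), so a Fitch node combination is a handful of
integer operations regardless of the number of characters.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .matrix_io import ABSENT, PRESENT, UNKNOWN, CharacterMatrix, OTULabel
from .tree import ANCESTOR_LABEL, Node, Tree

_INF = 1 << 40

CollapseRule = Literal["min-zero", "max-zero", "none"]


class ParsimonyError(ValueError):
    """Raised for invalid search or scoring inputs."""


# ---------------------------------------------------------------------------
# per-character step bounds and ensemble indices
# ---------------------------------------------------------------------------

def char_min_steps(column: str) -> int:
    """Minimum steps any tree needs for one binary column (unknowns excluded)."""
    return 1 if (ABSENT in column and PRESENT in column) else 0


def char_max_steps(column: str) -> int:
    """Maximum steps on the least informative (star) tree: min(#0s, #1s)."""
    return min(column.count(ABSENT), column.count(PRESENT))


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals, as printed fit indices are."""
    return math.floor(x * 100 + 1e-9) / 100


@dataclass(frozen=True)
class FitStatistics:
    """Ensemble fit of a character matrix on its most parsimonious trees.

    ``M`` is the sum of per-character minimum steps, ``G`` the sum of
    per-character maximum (star-tree) steps and ``S`` the tree length.
    CI = M/S, RI = (G-S)/(G-M). ``reported_*`` are the two-decimal
    truncations used in print. ``ci_informative`` excludes
    parsimony-uninformative characters, which contribute the same step
    count to every tree.
    """

    M: int
    G: int
    S: int
    ci: float
    ri: float
    reported_ci: float
    reported_ri: float
    ci_informative: float
    reported_ci_informative: float


def fit_statistics(S: int, m: CharacterMatrix) -> FitStatistics:
    """Ensemble indices for a tree of length ``S`` over matrix ``m``.

    The per-character step bounds are taken over the analyzed rows plus
    the hypothetical all-absent ancestor that roots every tree: the root
    is an OTU of the analysis (development starts organ-free), so it
    counts in the star-tree maxima G. It never affects M or S when a 0%
    row is present.
    """
    if all(char_min_steps(m.column(j)) == 0 for j in range(1, m.n_characters + 1)):
        raise ParsimonyError("all characters constant: fit indices undefined")
    mins = [char_min_steps(m.column(j) + ABSENT) for j in range(1, m.n_characters + 1)]
    maxs = [char_max_steps(m.column(j) + ABSENT) for j in range(1, m.n_characters + 1)]
    M, G = sum(mins), sum(maxs)
    ci = M / S
    ri = 1.0 if G == M else (G - S) / (G - M)
    # uninformative characters need exactly max(=min(n0,n1)<=1) steps on any tree
    uninf = [j for j in range(m.n_characters) if maxs[j] <= 1]
    S_u = sum(maxs[j] for j in uninf)
    M_i = M - sum(mins[j] for j in uninf)
    S_i = S - S_u
    ci_inf = M_i / S_i if S_i > 0 else 1.0
    return FitStatistics(
        M=M, G=G, S=S, ci=ci, ri=ri,
        reported_ci=truncate2(ci), reported_ri=truncate2(ri),
        ci_informative=ci_inf, reported_ci_informative=truncate2(ci_inf),
    )


# ---------------------------------------------------------------------------
# bitmask encoding and Fitch scoring of binary search trees
# ---------------------------------------------------------------------------

def _encode_row(row: str) -> tuple[int, int]:
    """Pack one state row into (zero-bits, one-bits); ``?`` sets both."""
    z = o = 0
    for j, s in enumerate(row):
        if s == ABSENT:
            z |= 1 << j
        elif s == PRESENT:
            o |= 1 << j
        elif s == UNKNOWN:
            z |= 1 << j
            o |= 1 << j
        else:  # pragma: no cover - construction-validated
            raise ParsimonyError(f"illegal state {s!r}")
    return z, o


class _SN:
    """Mutable binary search-tree node; ``pat`` indexes a leaf pattern."""

    __slots__ = ("parent", "children", "pat")

    def __init__(self, pat: Optional[int] = None,
                 children: Iterable["_SN"] = ()) -> None:
        self.pat = pat
        self.parent: Optional[_SN] = None
        self.children: list[_SN] = []
        for c in children:
            self.children.append(c)
            c.parent = self


def _score_top(top: _SN, zsets: list[int], osets: list[int], mask: int) -> int:
    """Fitch length of the tree whose root (the all-zero ancestor) has child ``top``."""
    cost = 0
    # iterative postorder; state sets stored per node id
    zs: dict[int, int] = {}
    os_: dict[int, int] = {}
    stack: list[tuple[_SN, bool]] = [(top, False)]
    while stack:
        node, done = stack.pop()
        if node.pat is not None:
            zs[id(node)] = zsets[node.pat]
            os_[id(node)] = osets[node.pat]
            continue
        if not done:
            stack.append((node, True))
            for c in node.children:
                stack.append((c, False))
        else:
            c0, c1 = node.children
            az, ao = zs.pop(id(c0)), os_.pop(id(c0))
            bz, bo = zs.pop(id(c1)), os_.pop(id(c1))
            iz, io = az & bz, ao & bo
            conflict = mask & ~(iz | io)
            cost += conflict.bit_count()
            zs[id(node)] = iz | ((az | bz) & conflict)
            os_[id(node)] = io | ((ao | bo) & conflict)
    # join with the all-zero ancestor: a step wherever 0 is not in the set
    cost += (mask & ~zs[id(top)]).bit_count()
    return cost


def _fitch_sets(az: int, ao: int, bz: int, bo: int,
                mask: int) -> tuple[int, int, int]:
    """Pairwise Fitch set combination; returns (z, o, conflict-bits)."""
    iz, io = az & bz, ao & bo
    conflict = mask & ~(iz | io)
    return iz | ((az | bz) & conflict), io | ((ao | bo) & conflict), conflict


def _edge_deltas(top: _SN, zsets, osets, mask: int,
                 xz: int, xo: int) -> tuple[int, list[tuple[_SN, int]]]:
    """Tree length plus the exact Fitch cost of inserting a new leaf on
    the edge above every node.

    A down pass computes per-node state sets and the current length; a
    preorder up pass computes the complement-tree sets. Their combination
    is the set of states optimally available on each edge, and inserting
    a leaf costs one extra step exactly for the characters whose leaf
    state set misses that edge set.
    """
    down: dict[int, tuple[int, int]] = {}
    cost = 0
    stack: list[tuple[_SN, bool]] = [(top, False)]
    while stack:
        node, done = stack.pop()
        if node.pat is not None:
            down[id(node)] = (zsets[node.pat], osets[node.pat])
            continue
        if not done:
            stack.append((node, True))
            for c in node.children:
                stack.append((c, False))
        else:
            a, b = node.children
            az, ao = down[id(a)]
            bz, bo = down[id(b)]
            z, o, conflict = _fitch_sets(az, ao, bz, bo, mask)
            cost += conflict.bit_count()
            down[id(node)] = (z, o)
    tz, _to = down[id(top)]
    cost += (mask & ~tz).bit_count()

    out: list[tuple[_SN, int]] = []
    up_stack: list[tuple[_SN, int, int]] = [(top, mask, 0)]  # ancestor is all-zero
    while up_stack:
        node, uz, uo = up_stack.pop()
        dz, do = down[id(node)]
        mz, mo, _ = _fitch_sets(uz, uo, dz, do, mask)
        delta = (mask & ~((xz & mz) | (xo & mo))).bit_count()
        out.append((node, delta))
        if node.pat is None:
            a, b = node.children
            az, ao = down[id(a)]
            bz, bo = down[id(b)]
            ua = _fitch_sets(uz, uo, bz, bo, mask)
            ub = _fitch_sets(uz, uo, az, ao, mask)
            up_stack.append((a, ua[0], ua[1]))
            up_stack.append((b, ub[0], ub[1]))
    return cost, out


def _iter_nodes(top: _SN) -> list[_SN]:
    out: list[_SN] = []
    stack = [top]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _insert_above(pos: _SN, leaf: _SN, top: _SN) -> tuple[_SN, _SN]:
    """Insert ``leaf`` on the edge above ``pos``; returns (new node, new top)."""
    parent = pos.parent
    newn = _SN(children=(pos, leaf))
    if parent is None:
        return newn, newn
    parent.children[parent.children.index(pos)] = newn
    newn.parent = parent
    return newn, top


def _remove_insertion(newn: _SN, leaf: _SN, top: _SN) -> _SN:
    """Undo :func:`_insert_above`."""
    pos = newn.children[0] if newn.children[1] is leaf else newn.children[1]
    parent = newn.parent
    if parent is None:
        pos.parent = None
        return pos
    parent.children[parent.children.index(newn)] = pos
    pos.parent = parent
    return top


def _canon(node: _SN):
    """Order-insensitive hashable form: (0, pat) leaves, (1, children) internals."""
    if node.pat is not None:
        return (0, node.pat)
    return (1, tuple(sorted(_canon(c) for c in node.children)))


def _build_from_canon(c) -> _SN:
    if c[0] == 0:
        return _SN(pat=c[1])
    return _SN(children=[_build_from_canon(x) for x in c[1]])


# ---------------------------------------------------------------------------
# search options / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchOptions:
    """Knobs for tree search.

    ``mode`` selects exact branch-and-bound or heuristic search;
    ``collapse_rule`` picks which zero-length branches are collapsed when
    condensing equally parsimonious trees (``min-zero`` collapses branches
    whose minimum optimized length is zero, ``max-zero`` only those that
    are zero under every optimal reconstruction); ``max_trees`` caps the
    number of retained trees; ``seed`` adds seeded random-addition
    replicates to the heuristic search.
    """

    mode: Literal["exact", "heuristic"] = "exact"
    collapse_rule: CollapseRule = "max-zero"
    max_trees: int = 100000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_trees < 1:
            raise ParsimonyError("max_trees must be >= 1")


@dataclass
class SearchResult:
    """All retained most-parsimonious trees plus their shared fit."""

    best_length: int
    trees: list[Tree]
    fit: FitStatistics
    capped: bool = False

    @property
    def n_trees(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# pattern merging
# ---------------------------------------------------------------------------

def _distinct_patterns(m: CharacterMatrix):
    """Merge identical rows.

    Returns (patterns, groups, zero_group): ``patterns[i]`` is the state
    row of search taxon i with ``groups[i]`` the OTUs sharing it; rows
    identical to the hypothetical all-absent ancestor are split off into
    ``zero_group`` and attach directly at the root.
    """
    all_zero = ABSENT * m.n_characters
    order: list[str] = []
    groups: dict[str, list[OTULabel]] = {}
    zero_group: list[OTULabel] = []
    for otu, row in zip(m.otus, m.rows):
        if row == all_zero:
            zero_group.append(otu)
            continue
        if row not in groups:
            groups[row] = []
            order.append(row)
        groups[row].append(otu)
    return order, [groups[r] for r in order], zero_group


def _expand_to_phylo(canon, groups: Sequence[Sequence[OTULabel]],
                     zero_group: Sequence[OTULabel]) -> Tree:
    """Rebuild a full tree: ancestor root, 0% OTUs as its children, merged
    rows re-expanded into small polytomies."""

    def build(c) -> Node:
        if c[0] == 0:
            members = groups[c[1]]
            if len(members) == 1:
                return Node(members[0].label)
            return Node(None, [Node(o.label) for o in members])
        return Node(None, [build(x) for x in c[1]])

    root = Node(ANCESTOR_LABEL)
    for otu in zero_group:
        root.add(Node(otu.label))
    root.add(build(canon))
    return Tree(root)


# ---------------------------------------------------------------------------
# general (polytomy-safe) dynamic programming on phylo trees
# ---------------------------------------------------------------------------

def _leaf_cost(row: str) -> np.ndarray:
    """(2, K) array: cost of assigning state 0 / 1 to this leaf."""
    k = len(row)
    cost = np.zeros((2, k), dtype=np.int64)
    for j, s in enumerate(row):
        if s == ABSENT:
            cost[1, j] = _INF
        elif s == PRESENT:
            cost[0, j] = _INF
    return cost


def _check_leaves(t: Tree, m: CharacterMatrix) -> None:
    labels = t.leaf_labels() - {ANCESTOR_LABEL}
    want = frozenset(m.labels())
    if labels != want:
        missing = sorted(want - labels)[:5]
        extra = sorted(labels - want)[:5]
        raise ParsimonyError(
            f"tree/matrix label mismatch (missing {missing}, extra {extra})"
        )


def _down_arrays(t: Tree, m: CharacterMatrix) -> dict[int, np.ndarray]:
    """Per-node (2, K) minimal subtree costs; exact for any node degree."""
    row_of = {o.label: r for o, r in zip(m.otus, m.rows)}
    down: dict[int, np.ndarray] = {}
    for n in t.root.postorder():
        if n.is_leaf:
            if n.label == ANCESTOR_LABEL:
                down[id(n)] = _leaf_cost(ABSENT * m.n_characters)
            else:
                down[id(n)] = _leaf_cost(row_of[n.label])
        else:
            acc = np.zeros((2, m.n_characters), dtype=np.int64)
            for c in n.children:
                dc = down[id(c)]
                acc += np.minimum(dc, dc[::-1] + 1)
            down[id(n)] = acc
    return down


def fitch_length(t: Tree, m: CharacterMatrix) -> int:
    """Parsimony length of ``t`` for matrix ``m`` (Fitch counting).

    Unknown cells contribute the full state set; the root, when it is the
    designated all-absent ancestor, is constrained to state 0 for every
    character (which never lengthens the tree when a 0% row is present).
    All-unknown characters cost zero. Polytomies are scored exactly.
    """
    _check_leaves(t, m)
    down = _down_arrays(t, m)
    droot = down[id(t.root)]
    if t.root.label == ANCESTOR_LABEL:
        per_char = droot[0]
    else:
        per_char = droot.min(axis=0)
    total = int(per_char.sum())
    if total >= _INF:
        raise ParsimonyError("inconsistent state assignment")
    return total


def _edge_change_bounds(t: Tree, m: CharacterMatrix):
    """Min and max optimized length of the edge above every non-root node.

    For each character and edge the DP asks whether a change on that edge
    is forced in every optimal reconstruction (contributes to the minimum
    length) or merely possible in some (contributes to the maximum).
    """
    down = _down_arrays(t, m)
    K = m.n_characters
    # P[v][t] = cost outside subtree(v) given parent(v) assigned t,
    # excluding the (parent, v) edge itself.
    P: dict[int, np.ndarray] = {}
    root = t.root
    root_cost = np.zeros((2, K), dtype=np.int64)
    if root.label == ANCESTOR_LABEL:
        root_cost[1, :] = _INF  # ancestor fixed to all-absent
    for n in t.root.preorder():
        if n.is_leaf:
            continue
        if n.parent is None:
            Q = root_cost
        else:
            Pn = P[id(n)]
            Q = np.minimum(Pn, Pn[::-1] + 1)  # now includes the edge above n
        sib_sum = np.zeros((2, K), dtype=np.int64)
        contribs = []
        for c in n.children:
            dc = down[id(c)]
            contribs.append(np.minimum(dc, dc[::-1] + 1))
            sib_sum += contribs[-1]
        for c, contrib in zip(n.children, contribs):
            P[id(c)] = Q + (sib_sum - contrib)
    min_len: dict[int, int] = {}
    max_len: dict[int, int] = {}
    for n in t.root.preorder():
        if n.parent is None:
            continue
        Pv, Dv = P[id(n)], down[id(n)]
        no_change = (Pv + Dv).min(axis=0)
        with_change = (Pv + Dv[::-1] + 1).min(axis=0)
        opt = np.minimum(no_change, with_change)
        min_len[id(n)] = int((no_change > opt).sum())
        max_len[id(n)] = int((with_change == opt).sum())
    return min_len, max_len


def condense_and_dedupe(trees: Iterable[Tree], m: CharacterMatrix,
                        rule: CollapseRule = "max-zero") -> list[Tree]:
    """Collapse zero-length branches and drop duplicate topologies.

    ``min-zero`` collapses every internal branch whose minimum length over
    all optimal reconstructions is zero (ambiguous support); ``max-zero``
    collapses only branches that are zero-length under every optimal
    reconstruction; ``none`` only deduplicates.
    """
    out: list[Tree] = []
    seen: set = set()
    for t in trees:
        t = t.copy()
        if rule != "none":
            min_len, max_len = _edge_change_bounds(t, m)
            score = min_len if rule == "min-zero" else max_len
            # collapse flagged internal edges (never leaf or root edges)
            for n in list(t.root.preorder()):
                if n.parent is None or n.is_leaf:
                    continue
                if score[id(n)] == 0:
                    parent = n.parent
                    i = parent.children.index(n)
                    parent.children.pop(i)
                    for j, c in enumerate(n.children):
                        c.parent = parent
                        parent.children.insert(i + j, c)
        key = t.canonical()
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# ACCTRAN character mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterChange:
    """A state change on the branch above a node."""

    char_index: int  # 1-based
    kind: Literal["gain", "loss"]


def acctran_changes(t: Tree, m: CharacterMatrix) -> dict[int, list[CharacterChange]]:
    """Map character changes onto branches under ACCTRAN optimization.

    Ambiguous placements are resolved by accelerating transformation:
    when assigning a node the parent's state or the opposite state costs
    the same, the opposite state is chosen, pushing gains rootward and
    favoring later reversals. Keys of the returned dict are ``id(node)``
    for the node below each changing branch; the total number of mapped
    changes equals the Fitch length.
    """
    _check_leaves(t, m)
    down = _down_arrays(t, m)
    K = m.n_characters
    final: dict[int, np.ndarray] = {}
    root_state = np.zeros(K, dtype=np.int64)
    if t.root.label != ANCESTOR_LABEL:
        root_state = np.asarray(down[id(t.root)].argmin(axis=0), dtype=np.int64)
    final[id(t.root)] = root_state
    changes: dict[int, list[CharacterChange]] = {}
    for n in t.root.preorder():
        if n.parent is None:
            continue
        f = final[id(n.parent)]
        dv = down[id(n)]
        idx = np.arange(K)
        same_cost = dv[f, idx]
        diff_cost = dv[1 - f, idx] + 1
        flip = diff_cost <= same_cost  # tie -> accelerate the change
        state = np.where(flip, 1 - f, f)
        final[id(n)] = state
        ch = [
            CharacterChange(int(j) + 1, "gain" if state[j] > f[j] else "loss")
            for j in np.nonzero(state != f)[0]
        ]
        if ch:
            changes[id(n)] = ch
    return changes


# ---------------------------------------------------------------------------
# heuristic search: stepwise addition + SPR branch swapping
# ---------------------------------------------------------------------------

def _stepwise_addition(order: Sequence[int], zsets, osets, mask) -> _SN:
    top: _SN = _SN(pat=order[0])
    for pat in order[1:]:
        leaf = _SN(pat=pat)
        best_pos, best_len = None, None
        for pos in _iter_nodes(top):
            newn, cand_top = _insert_above(pos, leaf, top)
            L = _score_top(cand_top, zsets, osets, mask)
            top = _remove_insertion(newn, leaf, cand_top)
            if best_len is None or L < best_len:
                best_pos, best_len = pos, L
        newn, top = _insert_above(best_pos, leaf, top)
    return top


def _spr_to_local_optimum(top: _SN, zsets, osets, mask,
                          equal_pool: Optional[set] = None,
                          pool_cap: int = 0) -> tuple[_SN, int]:
    """First-improvement subtree pruning and regrafting until stuck.

    Optionally records canonical forms of distinct equal-best trees
    encountered along the way (up to ``pool_cap``).
    """
    best = _score_top(top, zsets, osets, mask)
    if equal_pool is not None:
        equal_pool.add(_canon(top))
    improved = True
    while improved:
        improved = False
        for v in list(_iter_nodes(top)):
            if v.parent is None:
                continue
            parent = v.parent
            sib = parent.children[0] if parent.children[1] is v else parent.children[1]
            gp = parent.parent
            # prune v: splice its parent out of the tree
            v.parent = None
            if gp is None:
                sib.parent = None
                pruned_top = sib
            else:
                gp.children[gp.children.index(parent)] = sib
                sib.parent = gp
                pruned_top = top
            for pos in list(_iter_nodes(pruned_top)):
                newn, cand_top = _insert_above(pos, v, pruned_top)
                L = _score_top(cand_top, zsets, osets, mask)
                if L < best:
                    best = L
                    top = cand_top
                    if equal_pool is not None:
                        equal_pool.clear()
                        equal_pool.add(_canon(top))
                    improved = True
                    break
                if (L == best and equal_pool is not None
                        and len(equal_pool) < pool_cap):
                    equal_pool.add(_canon(cand_top))
                pruned_top = _remove_insertion(newn, v, cand_top)
            else:
                # no improving regraft: put v back where it was
                _newn, top = _insert_above(sib, v, pruned_top)
                continue
            break  # improved: restart the sweep from the new tree
    return top, best


def _prepare(m: CharacterMatrix):
    patterns, groups, zero_group = _distinct_patterns(m)
    if len(patterns) < 2:
        raise ParsimonyError("need at least 3 OTUs (2 distinct non-ancestral rows)")
    zsets, osets = [], []
    for row in patterns:
        z, o = _encode_row(row)
        zsets.append(z)
        osets.append(o)
    mask = (1 << m.n_characters) - 1
    return patterns, groups, zero_group, zsets, osets, mask


def heuristic_search(m: CharacterMatrix,
                     opts: SearchOptions = SearchOptions(mode="heuristic")
                     ) -> SearchResult:
    """Stepwise addition plus SPR branch swapping to a local optimum.

    Addition order is matrix row order; a non-None ``seed`` adds four
    seeded random-addition replicates. Deterministic for a fixed seed.
    """
    patterns, groups, zero_group, zsets, osets, mask = _prepare(m)
    n = len(patterns)
    orders = [list(range(n))]
    if opts.seed is not None:
        rng = random.Random(opts.seed)
        for _ in range(4):
            order = list(range(n))
            rng.shuffle(order)
            orders.append(order)
    best_len: Optional[int] = None
    pool: set = set()
    for order in orders:
        top = _stepwise_addition(order, zsets, osets, mask)
        local_pool: set = set()
        top, L = _spr_to_local_optimum(
            top, zsets, osets, mask, equal_pool=local_pool,
            pool_cap=opts.max_trees,
        )
        local_pool.add(_canon(top))
        if best_len is None or L < best_len:
            best_len = L
            pool = set(local_pool)
        elif L == best_len:
            pool |= local_pool
    capped = len(pool) > opts.max_trees
    canons = sorted(pool)[: opts.max_trees]
    expanded = [_expand_to_phylo(c, groups, zero_group) for c in canons]
    trees = condense_and_dedupe(expanded, m, opts.collapse_rule)
    return SearchResult(best_length=int(best_len), trees=trees,
                        fit=fit_statistics(int(best_len), m), capped=capped)


# ---------------------------------------------------------------------------
# exact search: branch and bound
# ---------------------------------------------------------------------------

def _bnb(taxa: Sequence[int], zsets, osets, mask, upper: int,
         all_trees: bool, max_trees: int):
    """Enumerate topologies by stepwise insertion with pruning.

    In all-trees mode partial trees longer than the bound are pruned and
    every completed tree at the best length is collected; in length-only
    mode partial trees reaching the bound are pruned (the bound is known
    to be achievable).
    """
    n = len(taxa)
    best = upper
    found: list = []
    capped = False
    top: _SN = _SN(pat=taxa[0])
    if n >= 2:
        top = _SN(children=(_SN(pat=taxa[0]), _SN(pat=taxa[1])))

    # Admissible completion bound per level: a character whose definite
    # presences all lie among not-yet-added taxa contributes zero steps to
    # the partial tree (the root is all-absent) but at least one to any
    # completion. extra[k] = number of such characters at level k.
    def1 = [o & ~z for z, o in zip(zsets, osets)]
    def0 = [z & ~o for z, o in zip(zsets, osets)]
    suffix = [0] * (n + 1)
    for k in range(n - 1, -1, -1):
        suffix[k] = suffix[k + 1] | def1[taxa[k]]
    prefix = 0
    uncov = [0] * (n + 1)
    extra = [0] * (n + 1)
    for k in range(n):
        uncov[k] = suffix[k] & ~prefix
        extra[k] = uncov[k].bit_count()
        prefix |= def1[taxa[k]]

    # Second bound term: two characters that fail the four-gamete test on
    # the full taxon set (the all-absent root supplies the (0,0) pair)
    # jointly need >= 3 steps on any tree. A matching over incompatible
    # pairs of still-uncovered characters adds one step per pair beyond
    # the one step each already counted in ``extra``.
    nchar = mask.bit_count()
    col1 = [0] * nchar
    col0 = [0] * nchar
    for i in range(n):
        for c in range(nchar):
            bit = 1 << c
            if def1[i] & bit:
                col1[c] |= 1 << i
            if def0[i] & bit:
                col0[c] |= 1 << i
    incompat: dict[int, int] = {c: 0 for c in range(nchar)}
    for a in range(nchar):
        for b in range(a + 1, nchar):
            if (col1[a] & col1[b]) and (col1[a] & col0[b]) and (col0[a] & col1[b]):
                incompat[a] |= 1 << b
                incompat[b] |= 1 << a
    bonus = [0] * (n + 1)
    for k in range(n + 1):
        avail = uncov[k] if k < n else 0
        pairs = 0
        while avail:
            c = (avail & -avail).bit_length() - 1
            avail &= avail - 1
            partners = incompat[c] & avail
            if partners:
                p = (partners & -partners).bit_length() - 1
                avail &= ~(1 << p)
                pairs += 1
        bonus[k] = pairs
        extra[k] += pairs

    def record(L: int) -> None:
        nonlocal best, capped, found
        if L < best:
            best = L
            found = []
            capped = False
        if L == best and all_trees:
            if len(found) < max_trees:
                found.append(_canon(top))
            else:
                capped = True
        elif L == best and not found:
            found.append(_canon(top))

    def rec(k: int, length: int) -> None:
        nonlocal top
        if k == n:
            record(length)
            return
        pat = taxa[k]
        _l, deltas = _edge_deltas(top, zsets, osets, mask, zsets[pat], osets[pat])
        leaf = _SN(pat=pat)
        lb_extra = extra[k + 1]
        for pos, d in deltas:
            L = length + d
            # once the tree cap is hit only strictly better trees matter
            keep_ties = all_trees and not capped
            ok = (L + lb_extra <= best) if keep_ties else (L + lb_extra < best)
            if ok:
                newn, top = _insert_above(pos, leaf, top)
                rec(k + 1, L)
                top = _remove_insertion(newn, leaf, top)

    if n == 1:
        record(_score_top(top, zsets, osets, mask))
    else:
        rec(2, _score_top(top, zsets, osets, mask))
    return best, found, capped


def branch_and_bound_search(m: CharacterMatrix,
                            opts: SearchOptions = SearchOptions()
                            ) -> SearchResult:
    """Exact search returning all most-parsimonious condensed trees.

    Taxon insertion order is by decreasing presence count (most derived
    first) for pruning power; the initial upper bound is the heuristic
    search result. With ``mode="heuristic"`` in ``opts`` this function
    dispatches to :func:`heuristic_search`.
    """
    if opts.mode == "heuristic":
        return heuristic_search(m, opts)
    patterns, groups, zero_group, zsets, osets, mask = _prepare(m)
    n = len(patterns)
    # upper bound from the heuristic; insertion order adds the least
    # developed OTUs first so uncovered late characters keep the
    # completion bound tight
    hopts = replace(opts, mode="heuristic", max_trees=1)
    upper = heuristic_search(m, hopts).best_length
    order = sorted(range(n), key=lambda i: ((osets[i] & ~zsets[i]).bit_count(), i))
    best, found, capped = _bnb(order, zsets, osets, mask, upper,
                               all_trees=True, max_trees=opts.max_trees)
    expanded = [_expand_to_phylo(c, groups, zero_group) for c in sorted(found)]
    trees = condense_and_dedupe(expanded, m, opts.collapse_rule)
    return SearchResult(best_length=int(best), trees=trees,
                        fit=fit_statistics(int(best), m), capped=capped)


def exact_best_length(m: CharacterMatrix) -> int:
    """Optimal tree length by bound-assisted branch and bound (length only).

    Uses the heuristic length as the incumbent and prunes any partial tree
    that reaches it, so the search only has to certify optimality (or find
    something shorter). Much faster than enumerating all optimal trees.
    """
    patterns, groups, zero_group, zsets, osets, mask = _prepare(m)
    n = len(patterns)
    upper = heuristic_search(m, SearchOptions(mode="heuristic", max_trees=1)).best_length
    order = sorted(range(n), key=lambda i: ((osets[i] & ~zsets[i]).bit_count(), i))
    best, _found, _capped = _bnb(order, zsets, osets, mask, upper,
                                 all_trees=False, max_trees=1)
    return int(best)


def ensemble_indices(result: SearchResult, m: CharacterMatrix) -> FitStatistics:
    """CI and RI for a finished search (all characters; truncated reporting)."""
    if result.n_trees == 0 and result.best_length is None:
        raise ParsimonyError("empty search result")
    return fit_statistics(result.best_length, m)
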