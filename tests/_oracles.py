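"""Independent brute-force oracles used to validate the fast implementation.

Everything here works on plain nested tuples and per-character recursion,
deliberately sharing no code with the package's bitmask/numpy paths.
"""

from __future__ import annotations

from itertools import product


def insert_everywhere(topo, x):
    """All ways to insert leaf ``x`` on an edge of a nested-tuple topology."""
    yield (topo, x)
    if isinstance(topo, tuple):
        a, b = topo
        for a2 in insert_everywhere(a, x):
            yield (a2, b)
        for b2 in insert_everywhere(b, x):
            yield (a, b2)


def all_topologies(leaf_ids):
    """Every binary topology (rooted at the implicit ancestor) over the ids."""
    topos = [leaf_ids[0]]
    for x in leaf_ids[1:]:
        topos = [t2 for t in topos for t2 in insert_everywhere(t, x)]
    return topos


def _char_cost(topo, states, s):
    """Min changes in the subtree when its root takes state ``s``.

    ``states[i]`` is the allowed state set of leaf i (e.g. {0}, {1} or
    {0, 1} for missing data).
    """
    if not isinstance(topo, tuple):
        return 0 if s in states[topo] else 10**9
    a, b = topo
    return min(_char_cost(a, states, t) + (t != s) for t in (0, 1)) + min(
        _char_cost(b, states, t) + (t != s) for t in (0, 1)
    )


def char_length(topo, states, root_state=None):
    """Optimal changes for one character; ``root_state`` pins the state of
    an ancestor attached above the topology's root."""
    if root_state is None:
        return min(_char_cost(topo, states, s) for s in (0, 1))
    return min(
        _char_cost(topo, states, s) + (s != root_state) for s in (0, 1)
    )


def leaf_state_sets(row: str):
    return [
        {0, 1} if c == "?" else {int(c)}
        for c in row
    ]


def _char_cost_memo(topo, states, s, j, memo):
    key = (topo, s, j)
    if key in memo:
        return memo[key]
    if not isinstance(topo, tuple):
        v = 0 if s in states[topo] else 10**9
    else:
        a, b = topo
        v = min(
            _char_cost_memo(a, states, t, j, memo) + (t != s) for t in (0, 1)
        ) + min(_char_cost_memo(b, states, t, j, memo) + (t != s) for t in (0, 1))
    memo[key] = v
    return v


def tree_length(topo, rows, rooted_at_ancestor=True, memo=None):
    """Total parsimony length of a topology over string rows.

    ``rows[i]`` is the state string of leaf i; with
    ``rooted_at_ancestor`` an all-zero ancestor is attached above the
    topology (the package's rooting convention). ``memo`` may be shared
    across topologies of the same matrix (subtrees recur).
    """
    k = len(rows[0])
    total = 0
    for j in range(k):
        states = {
            i: ({0, 1} if r[j] == "?" else {int(r[j])})
            for i, r in enumerate(rows)
        }
        m = memo.setdefault(j, {}) if memo is not None else {}
        per_state = [
            _char_cost_memo(topo, states, s, j, m) + (
                (s != 0) if rooted_at_ancestor else 0
            )
            for s in (0, 1)
        ]
        total += min(per_state)
    return total


def exhaustive_mp(rows):
    """All most parsimonious ancestor-rooted topologies by enumeration."""
    n = len(rows)
    best = None
    trees = []
    memo: dict = {}
    for topo in all_topologies(list(range(n))):
        L = tree_length(topo, rows, memo=memo)
        if best is None or L < best:
            best, trees = L, [topo]
        elif L == best:
            trees.append(topo)
    return best, trees


def topo_canonical(topo):
    """Hashable order-insensitive form of a nested-tuple topology."""
    if not isinstance(topo, tuple):
        return topo
    return frozenset((topo_canonical(topo[0]), topo_canonical(topo[1])))


def all_reconstructions(topo, states, root_state=0):
    """Every optimal internal-state assignment for one character.

    Returns (optimal length, list of assignments), each assignment a dict
    mapping internal nodes (by nested tuple) and leaves to states.
    """
    internals = []

    def collect(t):
        if isinstance(t, tuple):
            internals.append(t)
            collect(t[0])
            collect(t[1])

    collect(topo)

    def cost_of(assign):
        total = 0

        def state_of(t):
            if isinstance(t, tuple):
                return assign[t]
            return None  # leaf: handled below

        def walk(t, parent_state):
            nonlocal total
            if isinstance(t, tuple):
                s = assign[t]
                total += s != parent_state
                walk(t[0], s)
                walk(t[1], s)
            else:
                allowed = states[t]
                if parent_state in allowed:
                    pass
                elif len(allowed) == 1:
                    total += 1
                # missing-data leaf matches anything

        walk(topo, root_state)
        return total

    best = None
    solutions = []
    for combo in product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        c = cost_of(assign)
        if best is None or c < best:
            best, solutions = c, [assign]
        elif c == best:
            solutions.append(assign)
    return best, solutions
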