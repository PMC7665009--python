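"""Strict consensus of equally parsimonious rooted trees.

The strict consensus contains exactly the clusters (rooted clades) shared
by every input tree; all conflicting or unshared groupings collapse into
polytomies. Clusters rather than unrooted bipartitions are used because
every analysis here is rooted at the all-absent ancestor.
"""

from __future__ import annotations

from typing import Sequence

from .tree import Node, Tree, from_newick, to_newick  # noqa: F401  (re-export)


class ConsensusError(ValueError):
    """Input trees disagree on their leaf sets (or no trees given)."""


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Build the strict consensus of rooted trees on a common leaf set."""
    if not trees:
        raise ConsensusError("need at least one tree")
    leaf_set = trees[0].leaf_labels()
    for t in trees[1:]:
        if t.leaf_labels() != leaf_set:
            raise ConsensusError(
                "trees have differing leaf sets: "
                f"{sorted(leaf_set ^ t.leaf_labels())[:6]}"
            )
    shared = set.intersection(*(t.clusters() for t in trees))
    shared.add(frozenset(leaf_set))  # the root cluster always survives
    # nest clusters by size; each cluster attaches into the smallest
    # strictly containing one (strict consensus clusters are compatible)
    ordered = sorted(shared, key=len, reverse=True)
    nodes: dict[frozenset[str], Node] = {c: Node(None) for c in ordered}
    root_label = trees[0].root.label
    nodes[ordered[0]].label = root_label
    for i, c in enumerate(ordered):
        for j in range(i - 1, -1, -1):
            if c < ordered[j]:
                nodes[ordered[j]].add(nodes[c])
                break
    for leaf in sorted(leaf_set):
        target = min((c for c in ordered if leaf in c), key=len)
        nodes[target].add(Node(leaf))
    return Tree(nodes[ordered[0]])
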