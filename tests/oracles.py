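"""Independent brute-force oracles used only by the tests.

Everything here is implemented from first principles on plain label sets
and parent walks — deliberately sharing no indexing code with the package
— so DP results can be checked against naive enumeration.
"""

from __future__ import annotations

import itertools
import random
from fractions import Fraction

from pks3evo.trees import TreeNode

INF = Fraction(1 << 40)


# ---------------------------------------------------------------------------
# naive species-tree bookkeeping
# ---------------------------------------------------------------------------

class NaiveSpecies:
    def __init__(self, tree: TreeNode):
        self.nodes = list(tree.postorder())
        self.leafsets = {id(n): frozenset(n.leaf_labels()) for n in self.nodes}
        self.parent = {id(n): n.parent for n in self.nodes}

    def under(self, x: TreeNode, y: TreeNode) -> bool:
        """y lies in the subtree of x (y == x included)."""
        return self.leafsets[id(y)] <= self.leafsets[id(x)]

    def incomparable(self, x: TreeNode, y: TreeNode) -> bool:
        return not self.under(x, y) and not self.under(y, x)

    def edge_distance(self, x: TreeNode, y: TreeNode) -> int:
        """Edges on the path from x down to its descendant y."""
        d = 0
        while y is not x:
            y = self.parent[id(y)]
            d += 1
        return d


def brute_force_dtl(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    sigma: dict[str, str],
    costs=(Fraction(0), Fraction(3, 2), Fraction(6), Fraction(1)),
    allow_transfer: bool = True,
):
    """Enumerate every (mapping, event-labeling) reconciliation.

    ``costs`` = (codivergence, duplication, transfer, loss).  Returns
    (min cost as Fraction, number of co-optimal solutions).
    """
    dc, du, tc, lc = (Fraction(c) for c in costs)
    ns = NaiveSpecies(species_tree)
    snodes = ns.nodes
    by_label = {n.label: n for n in snodes if n.is_leaf}

    gnodes = list(gene_tree.postorder())
    internal = [g for g in gnodes if not g.is_leaf]
    fixed = {id(g): by_label[sigma[g.label]] for g in gnodes if g.is_leaf}

    best, count = None, 0
    for assignment in itertools.product(snodes, repeat=len(internal)):
        image = dict(fixed)
        for g, x in zip(internal, assignment):
            image[id(g)] = x
        total = Fraction(0)
        ways = 1
        valid = True
        for g in internal:
            x = image[id(g)]
            z1, z2 = (image[id(c)] for c in g.children)
            options = []
            if x.children:
                x1, x2 = x.children
                for za, zb in ((z1, z2), (z2, z1)):
                    if ns.under(x1, za) and ns.under(x2, zb):
                        options.append(
                            dc
                            + lc * (ns.edge_distance(x1, za))
                            + lc * (ns.edge_distance(x2, zb))
                        )
            if ns.under(x, z1) and ns.under(x, z2):
                options.append(
                    du
                    + lc * ns.edge_distance(x, z1)
                    + lc * ns.edge_distance(x, z2)
                )
            if allow_transfer:
                for stay, moved in ((z1, z2), (z2, z1)):
                    if ns.under(x, stay) and ns.incomparable(x, moved):
                        options.append(tc + lc * ns.edge_distance(x, stay))
            if not options:
                valid = False
                break
            node_min = min(options)
            total += node_min
            ways *= options.count(node_min)
        if not valid:
            continue
        if best is None or total < best:
            best, count = total, ways
        elif total == best:
            count += ways
    return best, count


# ---------------------------------------------------------------------------
# random / exhaustive tree construction
# ---------------------------------------------------------------------------

def tree_from_shape(shape, labels) -> TreeNode:
    if isinstance(shape, tuple):
        return TreeNode(children=[tree_from_shape(s, labels) for s in shape])
    return TreeNode(label=labels[shape])


def all_rooted_topologies(labels) -> list[TreeNode]:
    """Every rooted binary topology over the given leaf labels."""

    def shapes(k):
        out = [0]
        for item in range(1, k):
            nxt = []
            for s in out:
                nxt.extend(_insert(s, item))
            out = nxt
        return out

    def _insert(s, item):
        yield (s, item)
        if isinstance(s, tuple):
            for r in _insert(s[0], item):
                yield (r, s[1])
            for r in _insert(s[1], item):
                yield (s[0], r)

    return [tree_from_shape(s, list(labels)) for s in shapes(len(labels))]


def random_topology(labels, rng: random.Random) -> TreeNode:
    labels = list(labels)
    nodes = [TreeNode(label=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


def naive_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Unrooted non-trivial splits, canonicalized — test-side recount."""
    every = frozenset(tree.leaf_labels())
    splits = set()
    for node in tree.postorder():
        if node.is_root:
            continue
        side = frozenset(node.leaf_labels())
        if len(side) >= 2 and len(every - side) >= 2:
            splits.add(min(side, every - side, key=lambda s: tuple(sorted(s))))
    return splits
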