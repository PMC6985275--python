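"""Rooted-tree toolkit: Newick I/O, rooting, weak-edge collapsing, clade
assignment, taxonomic presence/absence summaries and topology congruence.

Trees are held in a lightweight :class:`TreeNode` structure (parent/child
pointers, branch length, 0-100 branch support) so that the reconciliation
and simulation code can annotate and rearrange nodes freely.  Parsing and
bipartition cross-checks go through dendropy.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Iterator, Mapping

import dendropy
import pandas as pd

__all__ = [
    "TreeNode",
    "read_tree",
    "parse_newick",
    "write_tree",
    "to_newick",
    "root_tree",
    "collapse_weak_edges",
    "assign_phylo_clades",
    "class_presence_absence",
    "topology_congruence",
    "round_half_up",
]


class TreeNode:
    """A node of a rooted tree.

    Attributes
    ----------
    label : str or None
        Leaf name, or an optional internal-node name.
    length : float or None
        Length of the branch subtending this node.
    support : float or None
        Branch support on a 0-100 scale for the edge above this node.
    children, parent
        Tree structure; the root has ``parent is None``.

    Algorithms attach extra attributes (``time``, ``species`` ...) as needed.
    """

    def __init__(self, label=None, length=None, support=None, children=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        if children:
            for ch in children:
                self.add_child(ch)

    # -- structure ---------------------------------------------------------
    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "TreeNode") -> None:
        self.children.remove(node)
        node.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, include_root: bool = True) -> list["TreeNode"]:
        return [
            n
            for n in self.postorder()
            if not n.is_leaf and (include_root or not n.is_root)
        ]

    def find(self, label: str) -> "TreeNode | None":
        for n in self.postorder():
            if n.label == label:
                return n
        return None

    # -- copying -----------------------------------------------------------
    def copy(self) -> "TreeNode":
        new = TreeNode(self.label, self.length, self.support)
        for ch in self.children:
            new.add_child(ch.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.label or '*'} n_leaves={len(self.leaves())}>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _from_dendropy(dnode) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label is not None:
        label = dnode.label
    node = TreeNode(label=label, length=dnode.edge.length)
    for ch in dnode.child_nodes():
        node.add_child(_from_dendropy(ch))
    return node


def _extract_supports(root: TreeNode) -> str:
    """Interpret numeric internal-node labels as branch supports.

    Returns the detected dialect: ``"percent"`` (0-100 scale) or
    ``"fraction"`` (0-1 scale, rescaled to 0-100 on read), or ``"none"``
    when no numeric internal labels are present.
    """
    numeric: list[tuple[TreeNode, float]] = []
    for node in root.postorder():
        if node.is_leaf or node.is_root or node.label is None:
            continue
        try:
            numeric.append((node, float(node.label)))
        except ValueError:
            continue
    if not numeric:
        return "none"
    dialect = "fraction" if all(v <= 1.0 for _, v in numeric) else "percent"
    scale = 100.0 if dialect == "fraction" else 1.0
    for node, value in numeric:
        node.support = value * scale
        node.label = None
    return dialect


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode` tree.

    Supports may be encoded as internal-node labels either on a 0-100
    scale or as fractions in [0, 1]; the dialect is auto-detected and
    recorded on the returned root as ``root.support_dialect``.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.support_dialect = _extract_supports(root)
    return root


def read_tree(path) -> TreeNode:
    """Read a Newick file; see :func:`parse_newick` for support handling."""
    with open(path) as fh:
        return parse_newick(fh.read())


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}:;,' \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_num(x: float) -> str:
    return f"{x:.10g}"


def to_newick(tree: TreeNode, include_supports: bool = True) -> str:
    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            s = _quote_label(node.label or "")
        else:
            s = "(" + ",".join(rec(ch) for ch in node.children) + ")"
            if include_supports and node.support is not None and not node.is_root:
                s += _fmt_num(node.support)
            elif node.label is not None:
                s += _quote_label(node.label)
        if node.length is not None:
            s += ":" + _fmt_num(node.length)
        return s

    return rec(tree) + ";"


def write_tree(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _suppress_unifurcations(root: TreeNode) -> TreeNode:
    """Splice out internal nodes with a single child (root included)."""
    changed = True
    while changed:
        changed = False
        for node in list(root.postorder()):
            if node.is_leaf or len(node.children) != 1:
                continue
            child = node.children[0]
            if node.parent is None:
                child.parent = None
                if child.length is not None and node.length is not None:
                    child.length += node.length
                root = child
            else:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
                if child.length is not None and node.length is not None:
                    child.length += node.length
            changed = True
    return root


def root_tree(tree: TreeNode, outgroup) -> TreeNode:
    """Root (or re-root) a tree on the edge separating ``outgroup``.

    ``outgroup`` is a leaf label or an iterable of leaf labels that must be
    monophyletic in the unrooted sense.  The input tree is not modified.

    Raises
    ------
    ValueError
        If outgroup leaves are missing, cover the whole tree, or are not
        monophyletic (the error lists the intruding leaves).
    """
    tree = tree.copy()
    if isinstance(outgroup, str):
        og = {outgroup}
    else:
        og = set(outgroup)
    all_leaves = set(tree.leaf_labels())
    missing = og - all_leaves
    if missing:
        raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
    if og == all_leaves:
        raise ValueError("outgroup cannot contain every leaf")

    target = None
    for node in tree.postorder():
        if node.is_root:
            continue
        ls = set(node.leaf_labels())
        if ls == og or ls == all_leaves - og:
            target = node
            break
    if target is None:
        # diagnose: smallest clade containing the outgroup, on each rooting side
        best = None
        for node in tree.postorder():
            ls = set(node.leaf_labels())
            if og <= ls and (best is None or len(ls) < len(best)):
                best = ls
        intruders = sorted(best - og) if best else []
        raise ValueError(
            f"outgroup {sorted(og)} is not monophyletic; "
            f"intruding leaves: {intruders}"
        )

    if target.parent.is_root and len(target.parent.children) == 2:
        # already rooted on this edge; put the outgroup side first for
        # a canonical orientation
        root = target.parent
        root.children.sort(key=lambda ch: ch is not target)
        out_root = root
    else:
        out_root = _reroot_above(target)
    if set(out_root.children[0].leaf_labels()) != og:
        out_root.children.reverse()
    return out_root


def _reroot_above(node: TreeNode) -> TreeNode:
    """Place a new root on the edge above ``node`` (splitting its length)."""
    old_parent = node.parent
    path = []
    p = old_parent
    while p is not None:
        path.append(p)
        p = p.parent
    saved = [(n.length, n.support) for n in path]

    new_root = TreeNode()
    old_parent.remove_child(node)
    new_root.add_child(node)
    elen = node.length
    if elen is not None:
        node.length = elen / 2.0
        other_half = elen / 2.0
    else:
        other_half = None
    new_root.add_child(old_parent)
    old_parent.length = other_half
    old_parent.support = node.support

    # reverse the edges along the path to the old root
    for i in range(len(path) - 1):
        child, par = path[i], path[i + 1]
        par.children.remove(child)
    for i in range(len(path) - 1):
        child, par = path[i], path[i + 1]
        child.add_child(par)
        par.length, par.support = saved[i]
    return _suppress_unifurcations(new_root)


# ---------------------------------------------------------------------------
# Weak-edge collapsing
# ---------------------------------------------------------------------------

def collapse_weak_edges(tree: TreeNode, threshold: float = 98.0) -> TreeNode:
    """Contract every internal edge whose support is below ``threshold``.

    An edge at exactly the threshold survives.  Edges without a recorded
    support are kept.  Leaves are never touched; the result may be
    multifurcating.  The input tree is not modified.
    """
    tree = tree.copy()
    for node in list(tree.postorder()):
        if node.is_leaf or node.is_root:
            continue
        if node.support is not None and node.support < threshold:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for ch in node.children:
                ch.parent = parent
            node.children = []
            node.parent = None
    return tree


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------

def assign_phylo_clades(
    tree: TreeNode,
    support_threshold: float = 95.0,
    min_clade_size: int = 2,
    seed_taxa: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, str | None]:
    """Assign leaves to well-supported monophyletic clades.

    Default mode extracts the maximal clades whose subtending edge has
    support >= ``support_threshold`` and that contain at least
    ``min_clade_size`` leaves; remaining leaves map to ``None``.  Clades
    are numbered ``clade1, clade2, ...`` by the alphabetical order of their
    smallest member, so the assignment does not depend on the rotation of
    the input Newick string.

    Alternatively, ``seed_taxa`` maps curated clade names to seed leaves;
    each clade is then the full subtree under the MRCA of its seeds.
    """
    assignment: dict[str, str | None] = {lab: None for lab in tree.leaf_labels()}

    if seed_taxa is not None:
        for name, seeds in seed_taxa.items():
            mrca = _mrca(tree, set(seeds))
            for leaf in mrca.leaf_labels():
                if assignment.get(leaf) is not None:
                    raise ValueError(
                        f"leaf {leaf!r} claimed by both {assignment[leaf]!r} "
                        f"and {name!r}"
                    )
                assignment[leaf] = name
        return assignment

    groups: list[list[str]] = []

    def descend(node: TreeNode) -> None:
        if not node.is_root and not node.is_leaf:
            ok_support = node.support is not None and node.support >= support_threshold
            if ok_support and len(node.leaves()) >= min_clade_size:
                groups.append(sorted(node.leaf_labels()))
                return
        for ch in node.children:
            descend(ch)

    descend(tree)
    groups.sort(key=lambda g: g[0])
    for i, group in enumerate(groups, start=1):
        for leaf in group:
            assignment[leaf] = f"clade{i}"
    return assignment


def _mrca(tree: TreeNode, labels: set[str]) -> TreeNode:
    best = None
    for node in tree.postorder():
        if labels <= set(node.leaf_labels()):
            if best is None or len(node.leaves()) < len(best.leaves()):
                best = node
    if best is None:
        raise ValueError(f"labels {sorted(labels)} not all present in tree")
    return best


# ---------------------------------------------------------------------------
# Presence/absence summaries
# ---------------------------------------------------------------------------

def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def class_presence_absence(
    taxonomy: pd.DataFrame,
    classifications: pd.DataFrame,
    label: str = "type3_pks",
) -> pd.DataFrame:
    """Per-class / per-phylum counts of genomes with and without a gene.

    Parameters
    ----------
    taxonomy : DataFrame with columns genome_id, kingdom, phylum, class.
    classifications : DataFrame with columns genome_id, classification
        (one row per classified gene).
    label : the classification that counts as presence.

    Returns a tidy DataFrame with one row per class, per phylum and one
    ``overall`` row: columns level, phylum, name, n_without, n_with,
    percent_with (integer, half-up).  Genomes seen in ``classifications``
    but absent from the taxonomy go to an ``unclassified`` bucket with a
    warning.
    """
    tax = taxonomy.copy()
    hit_genomes = set(
        classifications.loc[
            classifications["classification"] == label, "genome_id"
        ]
    )
    known = set(tax["genome_id"])
    orphans = sorted(hit_genomes - known)
    if orphans:
        warnings.warn(
            f"{len(orphans)} genome(s) missing from the taxonomy table; "
            f"counted as 'unclassified': {orphans[:5]}"
        )
        extra = pd.DataFrame(
            {
                "genome_id": orphans,
                "kingdom": "unclassified",
                "phylum": "unclassified",
                "class": "unclassified",
            }
        )
        tax = pd.concat([tax, extra], ignore_index=True)

    tax = tax.assign(present=tax["genome_id"].isin(hit_genomes))

    def _row(level, phylum, name, sub):
        n_with = int(sub["present"].sum())
        n_without = len(sub) - n_with
        pct = round_half_up(100.0 * n_with / len(sub)) if len(sub) else 0
        return {
            "level": level,
            "phylum": phylum,
            "name": name,
            "n_without": n_without,
            "n_with": n_with,
            "percent_with": pct,
        }

    rows = []
    for (phylum, cls), sub in sorted(tax.groupby(["phylum", "class"])):
        rows.append(_row("class", phylum, cls, sub))
    for phylum, sub in sorted(tax.groupby("phylum")):
        rows.append(_row("phylum", phylum, phylum, sub))
    rows.append(_row("overall", "", "overall", tax))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Topology congruence
# ---------------------------------------------------------------------------

def _prune_to(tree: TreeNode, keep: set[str]) -> TreeNode:
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if node.is_leaf and node.label not in keep and node.parent is not None:
                node.parent.remove_child(node)
                changed = True
        tree = _suppress_unifurcations(tree)
    return tree


def nontrivial_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Unrooted, non-trivial bipartitions as canonical frozensets of labels."""
    all_leaves = frozenset(tree.leaf_labels())
    splits = set()
    for node in tree.postorder():
        if node.is_root:
            continue
        side = frozenset(node.leaf_labels())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return splits


def topology_congruence(
    tree_a: TreeNode,
    tree_b: TreeNode,
    leaf_pairing: Mapping[str, str],
) -> float:
    """Normalized Robinson-Foulds distance in [0, 1] on paired leaves.

    ``leaf_pairing`` maps leaves of ``tree_a`` to leaves of ``tree_b`` (a
    bijection on a shared subset of size >= 4).  Both trees are restricted
    to the paired leaves, B is relabeled through the pairing, and the
    symmetric difference of non-trivial bipartitions is divided by the
    total number of non-trivial bipartitions in both restricted trees.
    """
    pairs = dict(leaf_pairing)
    if len(pairs) < 4:
        raise ValueError("leaf pairing must cover at least 4 shared leaves")
    if len(set(pairs.values())) != len(pairs):
        raise ValueError("leaf pairing is not a bijection")
    a_labels = set(tree_a.leaf_labels())
    b_labels = set(tree_b.leaf_labels())
    for a, b in pairs.items():
        if a not in a_labels:
            raise ValueError(f"leaf {a!r} not in first tree")
        if b not in b_labels:
            raise ValueError(f"leaf {b!r} not in second tree")

    sub_a = _prune_to(tree_a, set(pairs))
    sub_b = _prune_to(tree_b, set(pairs.values()))
    inverse = {b: a for a, b in pairs.items()}
    for leaf in sub_b.leaves():
        leaf.label = inverse[leaf.label]

    splits_a = nontrivial_bipartitions(sub_a)
    splits_b = nontrivial_bipartitions(sub_b)
    denom = len(splits_a) + len(splits_b)
    if denom == 0:
        return 0.0
    return len(splits_a ^ splits_b) / denom
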