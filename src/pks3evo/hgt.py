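"""Horizontal-gene-transfer screening.

Two independent signals are used: (1) tree structure — maximal clades of
the focal kingdom nested inside a subtree dominated by another kingdom
(e.g. fungal type III PKSs inside the bacterial clade), and (2) best-hit
tables — proteins whose best database hit belongs to another kingdom
(or, within the kingdom, another phylum) at high identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .trees import TreeNode

__all__ = [
    "HitRecord",
    "HGTCandidate",
    "nested_foreign_clades",
    "screen_hit_table",
    "minimum_hgt_frequency",
]


@dataclass(frozen=True)
class HitRecord:
    """One best-hit row (blastp-style) with source and hit taxonomy."""

    protein_id: str
    source_kingdom: str
    source_phylum: str
    source_class: str
    hit_description: str
    hit_kingdom: str
    hit_phylum: str
    identity: float
    evalue: float

    def __post_init__(self):
        if not 0 <= self.identity <= 100:
            raise ValueError(f"{self.protein_id}: identity outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative e-value")


@dataclass
class HGTCandidate:
    """A focal-kingdom clade nested inside a foreign-dominated subtree."""

    leaves: list[str]
    sister_taxa: list[str]
    support: float | None
    dominant_kingdom: str
    dominant_fraction: float

    @property
    def size(self) -> int:
        return len(self.leaves)


def nested_foreign_clades(
    tree: TreeNode,
    focal_kingdom: str,
    kingdom_of: Mapping[str, str] | None = None,
    dominance: float = 0.9,
) -> list[HGTCandidate]:
    """Find maximal pure focal-kingdom clades nested in foreign subtrees.

    A candidate is a maximal clade whose leaves all belong to
    ``focal_kingdom`` while the remaining leaves of its parent clade are
    dominated (fraction > ``dominance``) by a single *different* kingdom.
    Leaf kingdoms come from ``kingdom_of`` or from a ``kingdom`` attribute
    on the leaves; an unlabeled leaf is an error.  Candidates are disjoint
    by construction (maximality).
    """

    def kingdom(leaf: TreeNode) -> str:
        if kingdom_of is not None and leaf.label in kingdom_of:
            return kingdom_of[leaf.label]
        k = getattr(leaf, "kingdom", None)
        if k is None:
            raise ValueError(f"leaf {leaf.label!r} has no kingdom label")
        return k

    leaf_kingdoms: dict[int, dict[str, int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leaf_kingdoms[id(node)] = {kingdom(node): 1}
        else:
            counts: dict[str, int] = {}
            for ch in node.children:
                for k, v in leaf_kingdoms[id(ch)].items():
                    counts[k] = counts.get(k, 0) + v
            leaf_kingdoms[id(node)] = counts

    def pure_focal(node: TreeNode) -> bool:
        counts = leaf_kingdoms[id(node)]
        return set(counts) == {focal_kingdom}

    candidates: list[HGTCandidate] = []

    def descend(node: TreeNode) -> None:
        if pure_focal(node):
            parent = node.parent
            if parent is None or parent.parent is None:
                # the whole tree, or one side of the root split: a clean
                # kingdom separation is not a nested clade
                return
            context = {
                k: v for k, v in leaf_kingdoms[id(parent)].items()
            }
            for k, v in leaf_kingdoms[id(node)].items():
                context[k] -= v
                if context[k] == 0:
                    del context[k]
            total = sum(context.values())
            if total == 0:
                return
            top_kingdom, top_n = max(context.items(), key=lambda kv: kv[1])
            frac = top_n / total
            if top_kingdom != focal_kingdom and frac > dominance:
                sisters = [
                    leaf
                    for ch in parent.children
                    if ch is not node
                    for leaf in ch.leaf_labels()
                ]
                candidates.append(
                    HGTCandidate(
                        leaves=node.leaf_labels(),
                        sister_taxa=sisters,
                        support=node.support,
                        dominant_kingdom=top_kingdom,
                        dominant_fraction=frac,
                    )
                )
            return  # maximal: do not descend into a pure clade
        for ch in node.children:
            descend(ch)

    descend(tree)
    return candidates


def screen_hit_table(
    hits: Iterable[HitRecord],
    min_identity: float = 50.0,
    max_evalue: float = 1e-20,
) -> pd.DataFrame:
    """Categorize best-hit rows as cross-kingdom / cross-phylum / none.

    Rows passing both thresholds are flagged ``cross_kingdom`` when the
    hit kingdom differs from the source kingdom, ``cross_phylum`` when the
    kingdom matches but the phylum differs, and ``none`` otherwise (also
    for rows failing a threshold).  Row order does not affect any row's
    category.
    """
    rows = []
    for h in hits:
        passes = h.identity >= min_identity and h.evalue <= max_evalue
        if not passes:
            category = "none"
        elif h.hit_kingdom != h.source_kingdom:
            category = "cross_kingdom"
        elif h.hit_phylum != h.source_phylum:
            category = "cross_phylum"
        else:
            category = "none"
        rows.append(
            {
                "protein_id": h.protein_id,
                "source_kingdom": h.source_kingdom,
                "source_phylum": h.source_phylum,
                "hit_description": h.hit_description,
                "hit_kingdom": h.hit_kingdom,
                "hit_phylum": h.hit_phylum,
                "identity": h.identity,
                "evalue": h.evalue,
                "category": category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "source_kingdom", "source_phylum",
            "hit_description", "hit_kingdom", "hit_phylum",
            "identity", "evalue", "category",
        ],
    )


def minimum_hgt_frequency(n_transfers: int, n_genes: int) -> int:
    """Inferred transfers per analyzed gene, as an integer percentage.

    With 37 inferred transfers among 522 type III PKSs this is the
    "minimum HGT frequency" of 7%.
    """
    from .trees import round_half_up

    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return round_half_up(100.0 * n_transfers / n_genes)
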