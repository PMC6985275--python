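"""BGC similarity networks and gene-cluster families.

The pairwise distance between two biosynthetic gene clusters combines
three components, re-weighted for type III PKS clusters like the type I
PKS class (J = 0.22, DSS = 0.76, AI = 0.02):

* **J** — Jaccard index over the sets of domain types;
* **DSS** — domain sequence similarity: within each domain type, instances
  are paired by maximum-total-similarity assignment, unmatched instances
  score 0, and every instance of an anchor domain (the type III PKS
  domains by default) carries double weight;
* **AI** — adjacency index: Jaccard over the sets of unordered adjacent
  domain-type pairs read along each cluster.

``distance = 1 - (wJ*J + wDSS*DSS + wAI*AI)``.  Families are the
connected components of the network with edges at ``distance <= cutoff``
(default 0.5); no affinity-propagation post-step is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "BGCGene",
    "BGCRecord",
    "DistanceWeights",
    "GeneClusterFamily",
    "BGCDistance",
    "bgc_distance",
    "distance_matrix",
    "build_families",
    "write_bgc_table",
    "read_bgc_table",
]

DEFAULT_ANCHORS = frozenset({"PF00195", "PF02797"})


@dataclass
class BGCGene:
    """One gene of a cluster with its ordered domain content."""

    gene_id: str
    domains: list[str]
    core: bool = False
    anchor: bool = False
    instance_ids: list[str] | None = None


@dataclass
class BGCRecord:
    """A predicted biosynthetic gene cluster as an ordered gene list."""

    bgc_id: str
    genome_id: str
    genes: list[BGCGene]
    anchor_domains: frozenset = DEFAULT_ANCHORS
    clade: str | None = None

    def domain_types(self) -> set[str]:
        return {d for g in self.genes for d in g.domains}

    def domain_sequence(self) -> list[str]:
        return [d for g in self.genes for d in g.domains]

    def noncore_domain_types(self) -> set[str]:
        return {d for g in self.genes if not g.core for d in g.domains}

    def instances_by_type(self) -> dict[str, list[str | None]]:
        out: dict[str, list[str | None]] = {}
        for g in self.genes:
            ids = g.instance_ids or [None] * len(g.domains)
            for d, inst in zip(g.domains, ids):
                out.setdefault(d, []).append(inst)
        return out


@dataclass(frozen=True)
class DistanceWeights:
    """Component weights, anchor multiplier and network cutoff."""

    jaccard: float = 0.22
    dss: float = 0.76
    adjacency: float = 0.02
    anchor_multiplier: float = 2.0
    cutoff: float = 0.5

    def __post_init__(self):
        if abs(self.jaccard + self.dss + self.adjacency - 1.0) > 1e-12:
            raise ValueError("component weights must sum to 1")
        if self.anchor_multiplier < 1:
            raise ValueError("anchor multiplier must be >= 1")
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must be in [0, 1]")


class BGCDistance(NamedTuple):
    jaccard: float
    dss: float
    adjacency: float
    distance: float


def _adjacency_pairs(record: BGCRecord) -> set[frozenset]:
    seq = record.domain_sequence()
    return {frozenset((a, b)) for a, b in zip(seq, seq[1:])}


def _similarity(
    lookup, inst_a: str | None, inst_b: str | None, dtype: str
) -> float:
    if lookup is None:
        return 1.0
    if inst_a is None or inst_b is None:
        raise ValueError(
            f"similarity lookup given but domain type {dtype!r} has "
            f"instances without identifiers"
        )
    if callable(lookup):
        return float(lookup(inst_a, inst_b))
    key = (inst_a, inst_b)
    if key in lookup:
        return float(lookup[key])
    rkey = (inst_b, inst_a)
    if rkey in lookup:
        return float(lookup[rkey])
    raise KeyError(f"no similarity entry for instance pair {inst_a!r}, {inst_b!r}")


def bgc_distance(
    a: BGCRecord,
    b: BGCRecord,
    weights: DistanceWeights = DistanceWeights(),
    similarity: Callable[[str, str], float] | Mapping | None = None,
) -> BGCDistance:
    """Compute (J, DSS, AI, distance) between two clusters.

    When ``similarity`` is ``None`` (no sequences available), instances of
    the same domain type count as identical (similarity 1) and the metric
    degenerates gracefully to a content/architecture comparison.  With
    empty adjacency sets on both sides, AI is 1 when the domain-type sets
    match and 0 otherwise, so identical single-domain clusters still have
    distance 0 and disjoint ones distance 1.
    """
    if not a.genes or not b.genes:
        raise ValueError("both BGCs must be non-empty")
    types_a, types_b = a.domain_types(), b.domain_types()
    union = types_a | types_b
    jaccard = len(types_a & types_b) / len(union) if union else 0.0

    adj_a, adj_b = _adjacency_pairs(a), _adjacency_pairs(b)
    if not adj_a and not adj_b:
        ai = 1.0 if types_a == types_b else 0.0
    else:
        ai = len(adj_a & adj_b) / len(adj_a | adj_b)

    anchors = a.anchor_domains | b.anchor_domains
    inst_a, inst_b = a.instances_by_type(), b.instances_by_type()
    num = den = 0.0
    for dtype in union:
        weight = weights.anchor_multiplier if dtype in anchors else 1.0
        la = inst_a.get(dtype, [])
        lb = inst_b.get(dtype, [])
        den += weight * max(len(la), len(lb))
        if not la or not lb:
            continue
        if similarity is None:
            num += weight * min(len(la), len(lb))
            continue
        sims = [
            [_similarity(similarity, ia, ib, dtype) for ib in lb]
            for ia in la
        ]
        if len(la) == 1 and len(lb) == 1:
            num += weight * sims[0][0]
        else:
            cost = [[-s for s in row] for row in sims]
            rows, cols = linear_sum_assignment(cost)
            num += weight * sum(sims[r][c] for r, c in zip(rows, cols))
    dss = num / den if den else 0.0

    dist = 1.0 - (
        weights.jaccard * jaccard + weights.dss * dss + weights.adjacency * ai
    )
    # clip float fuzz
    dist = min(1.0, max(0.0, dist))
    return BGCDistance(jaccard, dss, ai, dist)


def distance_matrix(
    bgcs: Sequence[BGCRecord],
    weights: DistanceWeights = DistanceWeights(),
    similarity=None,
) -> pd.DataFrame:
    ids = [r.bgc_id for r in bgcs]
    df = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(bgcs):
        for j in range(i + 1, len(bgcs)):
            d = bgc_distance(a, bgcs[j], weights, similarity).distance
            df.iloc[i, j] = d
            df.iloc[j, i] = d
    return df


@dataclass
class GeneClusterFamily:
    """A connected component of the BGC network at the distance cutoff."""

    family_id: str
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


def build_families(
    bgcs: Sequence[BGCRecord],
    weights: DistanceWeights = DistanceWeights(),
    similarity=None,
) -> list[GeneClusterFamily]:
    """Connected-component gene-cluster families at ``weights.cutoff``.

    An edge joins two clusters when their distance is <= the cutoff
    (boundary included); singletons become families of size 1.  Family
    ids are assigned by the alphabetical order of each component's
    smallest member, so the result is invariant to input order.
    """
    graph = nx.Graph()
    graph.add_nodes_from(r.bgc_id for r in bgcs)
    for i, a in enumerate(bgcs):
        for b in bgcs[i + 1:]:
            d = bgc_distance(a, b, weights, similarity).distance
            if d <= weights.cutoff:
                graph.add_edge(a.bgc_id, b.bgc_id)
    components = [sorted(comp) for comp in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    return [
        GeneClusterFamily(family_id=f"GCF{i + 1}", members=comp)
        for i, comp in enumerate(components)
    ]


# ---------------------------------------------------------------------------
# plain-text round-trip format
# ---------------------------------------------------------------------------

_BGC_COLUMNS = [
    "bgc_id", "genome_id", "clade", "gene_index", "gene_id",
    "domain_index", "domain_accession", "core_flag", "anchor_flag",
    "instance_id", "anchor_domains",
]


def write_bgc_table(bgcs: Iterable[BGCRecord], path) -> None:
    """Long-format TSV: one row per domain instance."""
    rows = []
    for rec in bgcs:
        anchors = ",".join(sorted(rec.anchor_domains))
        for g_idx, gene in enumerate(rec.genes):
            ids = gene.instance_ids or [""] * len(gene.domains)
            for d_idx, (acc, inst) in enumerate(zip(gene.domains, ids)):
                rows.append(
                    {
                        "bgc_id": rec.bgc_id,
                        "genome_id": rec.genome_id,
                        "clade": rec.clade or "",
                        "gene_index": g_idx,
                        "gene_id": gene.gene_id,
                        "domain_index": d_idx,
                        "domain_accession": acc,
                        "core_flag": int(gene.core),
                        "anchor_flag": int(gene.anchor),
                        "instance_id": inst or "",
                        "anchor_domains": anchors,
                    }
                )
    pd.DataFrame(rows, columns=_BGC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bgc_table(path) -> list[BGCRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: list[BGCRecord] = []
    for bgc_id, sub in df.groupby("bgc_id", sort=False):
        sub = sub.copy()
        sub["gene_index"] = sub["gene_index"].astype(int)
        sub["domain_index"] = sub["domain_index"].astype(int)
        sub = sub.sort_values(["gene_index", "domain_index"])
        genes = []
        for g_idx, gsub in sub.groupby("gene_index", sort=True):
            inst = [i or None for i in gsub["instance_id"]]
            genes.append(
                BGCGene(
                    gene_id=gsub["gene_id"].iloc[0],
                    domains=list(gsub["domain_accession"]),
                    core=bool(int(gsub["core_flag"].iloc[0])),
                    anchor=bool(int(gsub["anchor_flag"].iloc[0])),
                    instance_ids=None if all(i is None for i in inst) else inst,
                )
            )
        first = sub.iloc[0]
        records.append(
            BGCRecord(
                bgc_id=str(bgc_id),
                genome_id=first["genome_id"],
                genes=genes,
                anchor_domains=frozenset(
                    a for a in first["anchor_domains"].split(",") if a
                ),
                clade=first["clade"] or None,
            )
        )
    return records
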