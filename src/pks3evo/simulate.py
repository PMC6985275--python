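"""Synthetic-data generators with recorded ground truth.

Four generators feed the downstream analysis stages so the whole pipeline
is testable without any genome downloads:

* a birth-death species-tree simulator (ultrametric, conditioned on the
  number of extant species),
* a gene-family simulator that evolves a single root copy down the species
  tree under per-lineage duplication / transfer / loss rates, recording
  every event (a :class:`TrueHistory`),
* a support degrader that marks a chosen fraction of internal gene-tree
  edges as weak (support below the collapse threshold of 98),
* a clade-structured BGC generator emitting anchor + tailoring domain
  content with a deterministic pairwise-similarity model.

The simulation clock runs root-to-leaves with exponential waiting times per
lineage, so under a small duplication rate the expected number of surviving
duplications is the rate times the total species-tree branch length, which
the tests use as an analytic oracle.  Transfers are additive copies whose
recipient edge is drawn uniformly among the species edges alive at the
transfer time, which guarantees temporal feasibility by construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trees import TreeNode, round_half_up, to_newick, write_tree

__all__ = [
    "Event",
    "TrueHistory",
    "CladeProfile",
    "SimilarityModel",
    "simulate_species_tree",
    "simulate_gene_family",
    "degrade_gene_tree",
    "simulate_clade_bgcs",
    "emit_fixtures",
    "stage_seed",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministically expand one global seed into a per-stage seed.

    The stage name is hashed with CRC-32 and folded with the global seed
    below 2**31 so the same bundle is reproduced from the same seed.
    """
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_species: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    max_resamples: int = 1000,
) -> TreeNode:
    """Simulate a rooted, binary, ultrametric species tree.

    The process starts from the root bifurcation at time 0 and runs a
    constant-rate birth-death process until the number of extant lineages
    first reaches ``n_species``; the tree is then cut at a uniform point of
    the waiting interval to the next event, so all leaves are
    contemporaneous.  Replicates that go extinct are resampled up to
    ``max_resamples`` times.

    Leaves are labeled ``S1..Sn`` (left-to-right), internal nodes ``N1..``.
    Every node carries a ``time`` attribute (root = 0).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    if death_rate < 0:
        raise ValueError("death_rate must be >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_resamples):
        tree = _one_bd_tree(n_species, birth_rate, death_rate, rng)
        if tree is not None:
            _label_species_tree(tree)
            return tree
    raise RuntimeError(
        f"species-tree simulation failed to reach {n_species} surviving "
        f"lineages within {max_resamples} resamples"
    )


def _one_bd_tree(n, birth, death, rng) -> TreeNode | None:
    root = TreeNode()
    root.time = 0.0
    tips = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    for tip in tips:
        tip.time = None  # open lineage
        tip.birth = 0.0
    t = 0.0
    total = birth + death
    while len(tips) != n:
        dt = rng.exponential(1.0 / (len(tips) * total))
        t += dt
        tip = tips[rng.integers(len(tips))]
        if rng.random() < birth / total:
            tip.time = t
            tips.remove(tip)
            for _ in range(2):
                ch = tip.add_child(TreeNode())
                ch.time = None
                ch.birth = t
                tips.append(ch)
        else:
            tip.time = t
            tip.dead = True
            tips.remove(tip)
            if not tips:
                return None
    # cut at a uniform point of the next waiting interval
    t_stop = t + rng.uniform() * rng.exponential(1.0 / (len(tips) * total))
    for tip in tips:
        tip.time = t_stop
    _prune_dead(root)
    root = _suppress_single_child(root)
    if len(root.leaves()) != n:
        return None
    return root


def _prune_dead(node: TreeNode) -> bool:
    """Remove extinct subtrees; return True if any extant leaf survives."""
    if node.is_leaf:
        return not getattr(node, "dead", False)
    for ch in list(node.children):
        if not _prune_dead(ch):
            node.remove_child(ch)
    return bool(node.children)


def _suppress_single_child(root: TreeNode) -> TreeNode:
    for node in list(root.postorder()):
        if node.is_leaf or len(node.children) != 1:
            continue
        child = node.children[0]
        if node.parent is None:
            child.parent = None
            root = child
        else:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
    return root


def _label_species_tree(root: TreeNode) -> None:
    if root.parent is None and root.time != 0.0:
        shift = root.time
        for node in root.postorder():
            node.time -= shift
    n_leaf = n_int = 0
    for node in root.preorder():
        if node.is_leaf:
            n_leaf += 1
            node.label = f"S{n_leaf}"
        else:
            n_int += 1
            node.label = f"N{n_int}"
        node.length = None if node.is_root else node.time - node.parent.time


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length for n in tree.postorder() if n.length is not None)


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------

@dataclass
class Event:
    """One recorded simulator event."""

    etype: str  # duplication | transfer | loss
    time: float
    donor: str  # species node closing the edge the event happened on
    recipient: str | None = None  # species edge receiving a transfer copy


@dataclass
class TrueHistory:
    """Ground truth for one simulated gene family.

    ``*_visible`` counts are restricted to what a reconciliation of the
    surviving gene tree could in principle see: a duplication is visible
    when both daughter subtrees survive, a transfer when the recipient
    subtree survives, and a loss is counted for every co-divergence of a
    surviving lineage whose sister copy left no survivors.
    """

    duplications: list[Event] = field(default_factory=list)
    transfers: list[Event] = field(default_factory=list)
    losses: list[Event] = field(default_factory=list)
    dups_visible: int = 0
    transfers_visible: int = 0
    losses_visible: int = 0

    @property
    def n_duplications(self) -> int:
        return len(self.duplications)

    @property
    def n_transfers(self) -> int:
        return len(self.transfers)

    @property
    def n_losses(self) -> int:
        return len(self.losses)


def _species_edges(species_tree: TreeNode) -> list[TreeNode]:
    """Every non-root node defines the edge (parent, node)."""
    return [n for n in species_tree.postorder() if not n.is_root]


def simulate_gene_family(
    species_tree: TreeNode,
    dup_rate: float = 0.08,
    transfer_rate: float = 0.06,
    loss_rate: float = 0.05,
    seed: int = 0,
) -> tuple[TreeNode | None, TrueHistory]:
    """Evolve one gene copy down the species tree under D/T/L rates.

    Returns the pruned gene tree of surviving lineages (``None`` when the
    family goes extinct) and the full :class:`TrueHistory`.  Surviving
    leaves are labeled ``<species>_<copy index>``.  Internal gene nodes
    carry ``etype`` (codiv / duplication / transfer) and ``species``
    annotations on the *unpruned* tree; the pruned tree keeps plain
    structure plus leaf labels.
    """
    for r, name in [(dup_rate, "dup_rate"), (transfer_rate, "transfer_rate"),
                    (loss_rate, "loss_rate")]:
        if r < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    history = TrueHistory()
    edges = _species_edges(species_tree)
    times = {n.label: n.time for n in species_tree.postorder()}

    def edges_alive(t: float, exclude: TreeNode) -> list[TreeNode]:
        out = []
        for e in edges:
            if e is exclude:
                continue
            if e.parent.time < t < e.time:
                out.append(e)
        return out

    total_rate = dup_rate + transfer_rate + loss_rate

    def evolve(gnode: TreeNode, sedge: TreeNode, t0: float) -> None:
        """Simulate the lineage of ``gnode`` along species edge ``sedge``."""
        t = t0
        t_end = sedge.time
        while True:
            if total_rate > 0:
                dt = rng.exponential(1.0 / total_rate)
            else:
                dt = np.inf
            if t + dt >= t_end:
                break
            t += dt
            u = rng.random() * total_rate
            if u < loss_rate:
                gnode.etype = "loss"
                gnode.species = sedge.label
                history.losses.append(Event("loss", t, sedge.label))
                return
            if u < loss_rate + dup_rate:
                gnode.etype = "duplication"
                gnode.species = sedge.label
                gnode.time = t
                history.duplications.append(Event("duplication", t, sedge.label))
                for _ in range(2):
                    evolve(gnode.add_child(TreeNode()), sedge, t)
                return
            # transfer
            candidates = edges_alive(t, sedge)
            if not candidates:
                continue  # no contemporaneous edge to receive a copy
            recipient = candidates[rng.integers(len(candidates))]
            gnode.etype = "transfer"
            gnode.species = sedge.label
            gnode.time = t
            history.transfers.append(
                Event("transfer", t, sedge.label, recipient.label)
            )
            donor_child = gnode.add_child(TreeNode())
            donor_child.transfer_role = "donor"
            recip_child = gnode.add_child(TreeNode())
            recip_child.transfer_role = "recipient"
            evolve(donor_child, sedge, t)
            evolve(recip_child, recipient, t)
            return
        # reached the bottom of the species edge
        if sedge.is_leaf:
            gnode.etype = "extant"
            gnode.species = sedge.label
            return
        gnode.etype = "codiv"
        gnode.species = sedge.label
        gnode.time = t_end
        for sch in sedge.children:
            evolve(gnode.add_child(TreeNode()), sch, t_end)

    # the root copy starts at time 0; the species root's bifurcation is the
    # first co-divergence
    groot = TreeNode()
    groot.etype = "codiv"
    groot.species = species_tree.label
    groot.time = 0.0
    for sch in species_tree.children:
        evolve(groot.add_child(TreeNode()), sch, 0.0)

    _score_visibility(groot, history)
    pruned = _prune_gene_tree(groot)
    return pruned, history


def _score_visibility(groot: TreeNode, history: TrueHistory) -> None:
    survives: dict[int, bool] = {}
    for node in groot.postorder():
        if node.is_leaf:
            survives[id(node)] = node.etype == "extant"
        else:
            survives[id(node)] = any(survives[id(c)] for c in node.children)
    dups = trans = losses = 0
    for node in groot.postorder():
        if node.is_leaf:
            continue
        kid_survival = [survives[id(c)] for c in node.children]
        if node.etype == "duplication" and all(kid_survival):
            dups += 1
        elif node.etype == "transfer":
            recip = next(
                c for c in node.children
                if getattr(c, "transfer_role", None) == "recipient"
            )
            if survives[id(recip)]:
                trans += 1
        elif node.etype == "codiv" and sum(kid_survival) == 1:
            losses += 1
    history.dups_visible = dups
    history.transfers_visible = trans
    history.losses_visible = losses


def _prune_gene_tree(groot: TreeNode) -> TreeNode | None:
    """Keep surviving lineages only; suppress pass-through nodes."""

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.etype == "extant":
                leaf = TreeNode()
                leaf.species = node.species
                return leaf
            return None
        kept = [rec(c) for c in node.children]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = TreeNode(children=kept)
        new.etype = node.etype
        new.species = node.species
        return new

    pruned = rec(groot)
    if pruned is None:
        return None
    counter: dict[str, int] = {}
    for leaf in pruned.leaves():
        counter[leaf.species] = counter.get(leaf.species, 0) + 1
        leaf.label = f"{leaf.species}_{counter[leaf.species]}"
    return pruned


def gene_to_species_map(gene_tree: TreeNode) -> dict[str, str]:
    """Default leaf mapping for simulated labels (``S3_2`` -> ``S3``)."""
    return {lab: lab.rsplit("_", 1)[0] for lab in gene_tree.leaf_labels()}


# ---------------------------------------------------------------------------
# Support degradation
# ---------------------------------------------------------------------------

def degrade_gene_tree(
    gene_tree: TreeNode,
    weak_fraction: float = 0.3,
    support_low: float = 50.0,
    support_high: float = 100.0,
    seed: int = 0,
    weak_threshold: float = 98.0,
) -> TreeNode:
    """Assign supports so that a fixed fraction of internal edges is weak.

    Exactly ``round(weak_fraction * n_internal_edges)`` internal edges
    (chosen uniformly) get supports drawn uniformly in
    ``[support_low, weak_threshold)``; the rest get supports in
    ``[weak_threshold, support_high]``.  The leaf set is unchanged; the
    input tree is not modified.
    """
    if not 0 <= weak_fraction <= 1:
        raise ValueError("weak_fraction must be in [0, 1]")
    tree = gene_tree.copy()
    rng = np.random.default_rng(seed)
    internal = [n for n in tree.postorder() if not n.is_leaf and not n.is_root]
    n_weak = round_half_up(weak_fraction * len(internal))
    weak_idx = set(
        rng.choice(len(internal), size=n_weak, replace=False).tolist()
    ) if n_weak else set()
    for i, node in enumerate(internal):
        if i in weak_idx:
            node.support = float(rng.uniform(support_low, weak_threshold))
        else:
            node.support = float(rng.uniform(weak_threshold, support_high))
    return tree


# ---------------------------------------------------------------------------
# BGC content
# ---------------------------------------------------------------------------

@dataclass
class CladeProfile:
    """Clade-specific recipe for BGC domain content.

    ``core_pool`` maps tailoring-domain accessions to their per-BGC
    inclusion probability; ``noise_pool`` domains are each included with
    probability ``noise_prob``.  Anchor domains are always included exactly
    once per BGC, on a single core-flagged anchor gene.
    """

    clade_id: str
    anchor_domains: tuple[str, ...] = ("PF00195", "PF02797")
    core_pool: dict[str, float] = field(default_factory=dict)
    noise_pool: tuple[str, ...] = ()
    noise_prob: float = 0.1

    def __post_init__(self):
        for d, p in self.core_pool.items():
            if not 0 <= p <= 1:
                raise ValueError(f"inclusion probability for {d} not in [0,1]")
        if not 0 <= self.noise_prob <= 1:
            raise ValueError("noise_prob must be in [0,1]")


class SimilarityModel:
    """Deterministic pairwise similarity for simulated domain instances.

    Same-clade instance pairs score ``1 - noise*u`` and cross-clade pairs
    ``0.5*(1 - noise*u)`` where ``u`` in [0,1) is a deterministic hash of
    the unordered instance pair and the seed - so the model is symmetric
    and reproducible without storing a quadratic table.
    """

    def __init__(self, clade_of_instance: dict[str, str],
                 noise: float = 0.1, seed: int = 0):
        self.clade_of_instance = dict(clade_of_instance)
        self.noise = float(noise)
        self.seed = int(seed)

    def __call__(self, inst_a: str, inst_b: str) -> float:
        if inst_a == inst_b:
            return 1.0
        a, b = sorted((inst_a, inst_b))
        u = zlib.crc32(f"{self.seed}|{a}|{b}".encode()) / 2**32
        base = 1.0 - self.noise * u
        if self.clade_of_instance.get(a) != self.clade_of_instance.get(b):
            base *= 0.5
        return max(0.0, min(1.0, base))


def simulate_clade_bgcs(
    profiles: Sequence[CladeProfile],
    n_bgc_per_clade: int = 12,
    similarity_noise: float = 0.1,
    seed: int = 0,
    genomes: Sequence[str] | None = None,
):
    """Generate clade-structured BGC records plus a similarity model.

    Each BGC gets exactly one anchor gene (core-flagged, holding the anchor
    domains in order) placed first, followed by the sampled tailoring and
    noise genes (one domain per gene) in a random order drawn once per
    clade profile — shared within the clade so that BGCs with identical
    domain content are architecturally identical (adjacency index 1,
    distance 0), while the order still varies across clades and across
    differing inclusion draws.  Returns
    ``(list of BGCRecord, SimilarityModel)``.
    """
    from .bgc import BGCGene, BGCRecord  # local import to avoid a cycle

    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng(seed)
    records = []
    clade_of_instance: dict[str, str] = {}
    for profile in profiles:
        clade_pool = list(profile.core_pool) + list(profile.noise_pool)
        clade_order = {
            d: r for d, r in zip(
                clade_pool, rng.permutation(len(clade_pool)).tolist()
            )
        }
        for i in range(n_bgc_per_clade):
            bgc_id = f"{profile.clade_id}_bgc{i + 1}"
            genome = (
                genomes[len(records) % len(genomes)]
                if genomes
                else f"genome_{bgc_id}"
            )
            anchor = BGCGene(
                gene_id=f"{bgc_id}_g1",
                domains=list(profile.anchor_domains),
                core=True,
                anchor=True,
            )
            tail_domains = [
                d for d, p in profile.core_pool.items() if rng.random() < p
            ]
            tail_domains += [
                d for d in profile.noise_pool if rng.random() < profile.noise_prob
            ]
            tail_domains.sort(key=clade_order.__getitem__)
            genes = [anchor]
            for j, domain in enumerate(tail_domains, start=2):
                genes.append(
                    BGCGene(
                        gene_id=f"{bgc_id}_g{j}",
                        domains=[domain],
                        core=False,
                        anchor=False,
                    )
                )
            rec = BGCRecord(
                bgc_id=bgc_id,
                genome_id=genome,
                genes=genes,
                anchor_domains=frozenset(profile.anchor_domains),
                clade=profile.clade_id,
            )
            for g_idx, gene in enumerate(rec.genes):
                gene.instance_ids = [
                    f"{bgc_id}|{g_idx}|{d_idx}|{acc}"
                    for d_idx, acc in enumerate(gene.domains)
                ]
                for inst in gene.instance_ids:
                    clade_of_instance[inst] = profile.clade_id
            records.append(rec)
    model = SimilarityModel(clade_of_instance, similarity_noise, seed)
    return records, model


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

@dataclass
class SimulationBundle:
    """Everything one simulate run produces, ready to write to disk."""

    species_tree: TreeNode
    gene_trees: dict[str, TreeNode]
    histories: dict[str, TrueHistory]
    clade_of_family: dict[str, str]
    bgcs: list
    taxonomy: pd.DataFrame
    gene_table: pd.DataFrame
    domain_hits: pd.DataFrame
    background: pd.DataFrame


def emit_fixtures(bundle: SimulationBundle, out_dir) -> dict[str, Path]:
    """Write the bundle as plain-text fixtures; round-trips losslessly
    through the module readers (Newick, TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["species_tree"] = out / "species_tree.nwk"
    write_tree(bundle.species_tree, paths["species_tree"])

    gdir = out / "gene_trees"
    gdir.mkdir(exist_ok=True)
    for fam, tree in bundle.gene_trees.items():
        write_tree(tree, gdir / f"{fam}.nwk")
    paths["gene_trees"] = gdir

    for name, df in [
        ("taxonomy", bundle.taxonomy),
        ("gene_table", bundle.gene_table),
        ("background", bundle.background),
    ]:
        paths[name] = out / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)

    # the hit table is whitespace-delimited with a commented header, the
    # format parse_domain_hits documents
    paths["domain_hits"] = out / "domain_hits.tsv"
    with open(paths["domain_hits"], "w") as fh:
        fh.write("# protein_id accession evalue score start end\n")
        for r in bundle.domain_hits.itertuples():
            fh.write(
                f"{r.protein_id}\t{r.accession}\t{r.evalue:g}"
                f"\t{r.score:g}\t{r.start}\t{r.end}\n"
            )

    from .bgc import write_bgc_table

    paths["bgcs"] = out / "bgcs.tsv"
    write_bgc_table(bundle.bgcs, paths["bgcs"])

    truth_rows = [
        {
            "family_id": fam,
            "clade": bundle.clade_of_family[fam],
            "dups_visible": h.dups_visible,
            "transfers_visible": h.transfers_visible,
            "losses_visible": h.losses_visible,
            "dups_all": h.n_duplications,
            "transfers_all": h.n_transfers,
            "losses_all": h.n_losses,
        }
        for fam, h in bundle.histories.items()
    ]
    paths["truth"] = out / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
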