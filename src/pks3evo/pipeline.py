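"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes, in order: simulate -> classify -> trees ->
reconcile -> hgt -> families -> occur -> report.  Every stage reads its
inputs from the files the previous stages wrote, so deleting an
intermediate and re-running regenerates that stage and everything
downstream while leaving upstream outputs untouched.  All randomness
derives from the single config seed through a per-stage expansion, and
reports carry no timestamps, so a re-run with the same config is
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

from . import refdata
from .bgc import (
    BGCRecord, DistanceWeights, build_families, distance_matrix,
    read_bgc_table,
)
from .config import PipelineConfig, save_config
from .domains import classify_hits_table, detect_multi_pks_loci, GeneRecord, parse_domain_hits
from .hgt import minimum_hgt_frequency, nested_foreign_clades, screen_hit_table
from .occurrence import clade_spread, enrichment_scan, occurrence_table
from .reconcile import (
    CostScheme, format_event_table, reconcile_dl, reconcile_dtl,
    summarize_events,
)
from .simulate import (
    CladeProfile, SimulationBundle, degrade_gene_tree, emit_fixtures,
    simulate_clade_bgcs, simulate_gene_family, simulate_species_tree,
    stage_seed,
)
from .trees import (
    class_presence_absence, assign_phylo_clades, collapse_weak_edges,
    read_tree, write_tree,
)

__all__ = ["run_pipeline", "render_reports", "simulate_dataset", "STAGES"]

logger = logging.getLogger("pks3evo")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

_TAILORING_POOL = [
    "PF00067",  # cytochrome P450
    "PF07690",  # MFS transporter
    "PF00172",  # fungal Zn(2)-Cys(6) transcription factor
    "PF00107",  # zinc-binding dehydrogenase
    "PF13489",  # methyltransferase
    "PF00005",  # ABC transporter
    "PF01494",  # FAD-binding monooxygenase
    "PF08240",  # alcohol dehydrogenase GroES-like
]
_NOISE_POOL = ["PF00069", "PF06985", "PF12796", "PF12937", "PF00083"]


def _clade_profiles(n_clades: int) -> list[CladeProfile]:
    """Clade recipes: each clade gets a rotated slice of the tailoring
    pool at decreasing inclusion probabilities, plus shared noise."""
    profiles = []
    for i in range(n_clades):
        pool = {}
        for j, p in enumerate((0.95, 0.7, 0.4)):
            domain = _TAILORING_POOL[(2 * i + j) % len(_TAILORING_POOL)]
            pool[domain] = p
        profiles.append(
            CladeProfile(
                clade_id=f"clade{i + 1}",
                core_pool=pool,
                noise_pool=tuple(_NOISE_POOL),
                noise_prob=0.1,
            )
        )
    return profiles


def simulate_dataset(config: PipelineConfig) -> SimulationBundle:
    """Build one coherent synthetic dataset from the config conditions."""
    sp_tree = simulate_species_tree(
        config.n_species, config.birth_rate, config.death_rate,
        seed=stage_seed(config.seed, "species_tree"),
    )
    species = sp_tree.leaf_labels()

    gene_trees, histories, clade_of_family = {}, {}, {}
    for i in range(config.n_families):
        fam = f"fam{i + 1}"
        clade_of_family[fam] = f"clade{i % config.n_clades + 1}"
        for attempt in range(50):
            seed = stage_seed(config.seed, f"family:{fam}:{attempt}")
            tree, history = simulate_gene_family(
                sp_tree, config.dup_rate, config.transfer_rate,
                config.loss_rate, seed=seed,
            )
            if tree is not None and len(tree.leaves()) >= 2:
                break
        else:
            raise RuntimeError(f"family {fam}: no surviving tree in 50 tries")
        gene_trees[fam] = degrade_gene_tree(
            tree, config.weak_fraction, config.support_low,
            config.support_high,
            seed=stage_seed(config.seed, f"degrade:{fam}"),
            weak_threshold=config.collapse_threshold,
        )
        histories[fam] = history

    profiles = _clade_profiles(config.n_clades)
    bgcs, _similarity = simulate_clade_bgcs(
        profiles, config.n_bgc_per_clade, config.similarity_noise,
        seed=stage_seed(config.seed, "bgcs"), genomes=species,
    )

    taxonomy = _taxonomy_from_tree(sp_tree)
    gene_table, domain_hits = _genes_and_hits(bgcs)
    background = _background_counts(profiles)
    return SimulationBundle(
        species_tree=sp_tree, gene_trees=gene_trees, histories=histories,
        clade_of_family=clade_of_family, bgcs=bgcs, taxonomy=taxonomy,
        gene_table=gene_table, domain_hits=domain_hits,
        background=background,
    )


def _taxonomy_from_tree(sp_tree) -> pd.DataFrame:
    """Phylum = root split, class = split one level deeper."""
    rows = []
    root_children = sp_tree.children
    for p_idx, sub in enumerate(root_children):
        phylum = f"phylum{p_idx + 1}"
        class_groups = sub.children if sub.children else [sub]
        for c_idx, csub in enumerate(class_groups):
            cls = f"{phylum}_class{c_idx + 1}"
            for leaf in csub.leaves():
                rows.append(
                    {
                        "genome_id": leaf.label,
                        "kingdom": "Fungi",
                        "phylum": phylum,
                        "class": cls,
                    }
                )
    return pd.DataFrame(sorted(rows, key=lambda r: r["genome_id"]))


def _genes_and_hits(bgcs: list[BGCRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay BGC genes on one scaffold per cluster; derive domain hits.

    Adds two deterministic extras exercising the locus logic: a tandem
    pair of type III PKS genes in opposite orientations, and a partial
    protein carrying only one of the two signature domains.
    """
    gene_rows, hit_rows = [], []

    def add_gene(gene_id, genome, scaffold, start, end, strand, domains):
        gene_rows.append(
            {
                "gene_id": gene_id, "genome_id": genome,
                "scaffold": scaffold, "start": start, "end": end,
                "strand": strand,
            }
        )
        pos = 1
        for acc in domains:
            hit_rows.append(
                {
                    "protein_id": gene_id, "accession": acc,
                    "evalue": 1e-40, "score": 250.0,
                    "start": pos, "end": pos + 110,
                }
            )
            pos += 120

    for rec in bgcs:
        scaffold = f"{rec.bgc_id}_scaffold"
        for i, gene in enumerate(rec.genes):
            start = i * 1500
            strand = "+" if i % 2 == 0 else "-"
            add_gene(
                gene.gene_id, rec.genome_id, scaffold, start, start + 1200,
                strand, gene.domains,
            )
    genome = bgcs[0].genome_id if bgcs else "genomeX"
    add_gene("tandem_pks_a", genome, "tandem_scaffold", 0, 1200, "+",
             ["PF00195", "PF02797"])
    add_gene("tandem_pks_b", genome, "tandem_scaffold", 2000, 3200, "-",
             ["PF00195", "PF02797"])
    add_gene("partial_pks", genome, "partial_scaffold", 0, 900, "+",
             ["PF00195"])
    return pd.DataFrame(gene_rows), pd.DataFrame(hit_rows)


def _background_counts(profiles: list[CladeProfile]) -> pd.DataFrame:
    """Non-BGC proteome domain counts: noise domains are common in the
    background, tailoring domains rare — the contrast enrichment should
    recover."""
    rows = []
    for profile in profiles:
        for domain in profile.core_pool:
            rows.append(
                {
                    "clade": profile.clade_id, "domain": domain,
                    "background_with": 5, "background_total": 5000,
                }
            )
        for domain in profile.noise_pool:
            rows.append(
                {
                    "clade": profile.clade_id, "domain": domain,
                    "background_with": 400, "background_total": 5000,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage implementations (file-level, re-runnable)
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out: Path) -> None:
    bundle = simulate_dataset(config)
    emit_fixtures(bundle, out)
    save_config(config, out / "config.yaml")


def _stage_classify(config: PipelineConfig, out: Path) -> None:
    hits = parse_domain_hits(out / "domain_hits.tsv", config.evalue_cutoff)
    classified = classify_hits_table(hits)
    gene_table = pd.read_csv(out / "gene_table.tsv", sep="\t")
    merged = gene_table.merge(
        classified, left_on="gene_id", right_on="protein_id", how="left"
    )
    merged["classification"] = merged["classification"].fillna("other")
    merged[
        ["gene_id", "genome_id", "scaffold", "start", "end", "strand",
         "classification"]
    ].to_csv(out / "classifications.tsv", sep="\t", index=False)

    genes = [
        GeneRecord(
            gene_id=r.gene_id, genome_id=r.genome_id, scaffold=r.scaffold,
            start=int(r.start), end=int(r.end), strand=r.strand,
            classification=r.classification,
        )
        for r in merged.itertuples()
    ]
    loci = detect_multi_pks_loci(genes, config.max_gap_bp)
    pd.DataFrame(
        [
            {
                "genome_id": l.genome_id, "scaffold": l.scaffold,
                "n_genes": l.size, "strands": l.strand_pattern,
                "divergent_pair": l.divergent_pair,
                "genes": ",".join(g.gene_id for g in l.genes),
            }
            for l in loci
        ],
        columns=["genome_id", "scaffold", "n_genes", "strands",
                 "divergent_pair", "genes"],
    ).to_csv(out / "loci.tsv", sep="\t", index=False)

    taxonomy = pd.read_csv(out / "taxonomy.tsv", sep="\t")
    presence = class_presence_absence(
        taxonomy,
        merged.rename(columns={"gene_id": "gene"})[
            ["genome_id", "classification"]
        ],
    )
    presence.to_csv(out / "presence_absence.tsv", sep="\t", index=False)


def _stage_trees(config: PipelineConfig, out: Path) -> None:
    collapsed_dir = out / "collapsed_trees"
    collapsed_dir.mkdir(exist_ok=True)
    assign_rows = []
    for path in sorted((out / "gene_trees").glob("*.nwk")):
        tree = read_tree(path)
        collapsed = collapse_weak_edges(tree, config.collapse_threshold)
        write_tree(collapsed, collapsed_dir / path.name)
        clades = assign_phylo_clades(
            tree, config.clade_support_threshold, config.min_clade_size
        )
        for leaf, clade in sorted(clades.items()):
            assign_rows.append(
                {
                    "family_id": path.stem, "protein_id": leaf,
                    "clade": clade if clade else "unassigned",
                }
            )
    pd.DataFrame(
        assign_rows, columns=["family_id", "protein_id", "clade"]
    ).to_csv(out / "clade_assignments.tsv", sep="\t", index=False)


def _stage_reconcile(config: PipelineConfig, out: Path) -> None:
    species_tree = read_tree(out / "species_tree.nwk")
    truth = pd.read_csv(out / "truth.tsv", sep="\t").set_index("family_id")
    costs = CostScheme(
        duplication=config.cost_duplication, loss=config.cost_loss,
        transfer=config.cost_transfer,
        codivergence=config.cost_codivergence,
    )
    rows = []
    for path in sorted((out / "collapsed_trees").glob("*.nwk")):
        fam = path.stem
        gene_tree = read_tree(path)
        clade = truth.loc[fam, "clade"] if fam in truth.index else "unassigned"
        for model, fn in (("DTL", reconcile_dtl), ("DL", reconcile_dl)):
            res = fn(gene_tree, species_tree, costs=costs)
            rows.append(
                {
                    "family_id": fam, "clade": clade, "model": model,
                    "cost": res.cost,
                    "codivergences": res.codivergences,
                    "duplications": res.duplications,
                    "transfers": res.transfers,
                    "losses": res.losses,
                    "n_optimal": res.n_optimal,
                    "feasible": res.feasible,
                }
            )
    events = pd.DataFrame(rows)
    events.to_csv(out / "family_events.tsv", sep="\t", index=False)
    summary = summarize_events(events)
    summary.to_csv(out / "event_summary.tsv", sep="\t", index=False)


def _stage_hgt(config: PipelineConfig, out: Path) -> None:
    taxonomy = pd.read_csv(out / "taxonomy.tsv", sep="\t")
    kingdom_of = dict(zip(taxonomy["genome_id"], taxonomy["kingdom"]))
    species_tree = read_tree(out / "species_tree.nwk")
    candidates = nested_foreign_clades(
        species_tree, "Fungi", kingdom_of, config.hgt_dominance
    )
    pd.DataFrame(
        [
            {
                "leaves": ",".join(c.leaves),
                "sister_taxa": ",".join(c.sister_taxa),
                "support": c.support,
                "dominant_kingdom": c.dominant_kingdom,
                "dominant_fraction": c.dominant_fraction,
            }
            for c in candidates
        ],
        columns=["leaves", "sister_taxa", "support", "dominant_kingdom",
                 "dominant_fraction"],
    ).to_csv(out / "hgt_candidates.tsv", sep="\t", index=False)
    screened = screen_hit_table(
        refdata.hgt_hit_records(), config.hgt_min_identity,
        config.hgt_max_evalue,
    )
    screened.to_csv(out / "hgt_hits.tsv", sep="\t", index=False)


def _weights(config: PipelineConfig) -> DistanceWeights:
    return DistanceWeights(
        jaccard=config.weight_jaccard, dss=config.weight_dss,
        adjacency=config.weight_adjacency,
        anchor_multiplier=config.anchor_multiplier,
        cutoff=config.distance_cutoff,
    )


def _stage_families(config: PipelineConfig, out: Path) -> None:
    bgcs = read_bgc_table(out / "bgcs.tsv")
    weights = _weights(config)
    rows = []
    matrices = []
    for clade in sorted({r.clade or "unassigned" for r in bgcs}):
        clade_bgcs = [r for r in bgcs if (r.clade or "unassigned") == clade]
        families = build_families(clade_bgcs, weights)
        for fam in families:
            for member in fam.members:
                rows.append(
                    {
                        "clade": clade,
                        "family_id": f"{clade}_{fam.family_id}",
                        "bgc_id": member,
                        "family_size": fam.size,
                    }
                )
        dm = distance_matrix(clade_bgcs, weights)
        dm.insert(0, "bgc_id", dm.index)
        matrices.append(dm)
    pd.DataFrame(
        rows, columns=["clade", "family_id", "bgc_id", "family_size"]
    ).to_csv(out / "families.tsv", sep="\t", index=False)
    pd.concat(matrices).to_csv(
        out / "distances.tsv", sep="\t", index=False
    )


def _stage_occur(config: PipelineConfig, out: Path) -> None:
    from .bgc import GeneClusterFamily

    bgcs = read_bgc_table(out / "bgcs.tsv")
    lookup = {r.bgc_id: r for r in bgcs}
    fam_df = pd.read_csv(out / "families.tsv", sep="\t")
    families_by_clade: dict[str, list[GeneClusterFamily]] = {}
    for (clade, fam_id), sub in fam_df.groupby(["clade", "family_id"]):
        families_by_clade.setdefault(clade, []).append(
            GeneClusterFamily(family_id=fam_id, members=sorted(sub["bgc_id"]))
        )
    occ = occurrence_table(families_by_clade, lookup)
    occ.table.to_csv(out / "occurrence.tsv", sep="\t", index=False)
    clade_spread(occ).to_csv(out / "clade_spread.tsv", sep="\t", index=False)

    background = pd.read_csv(out / "background.tsv", sep="\t")
    count_rows = []
    for clade, bg in background.groupby("clade"):
        clade_bgcs = [r for r in bgcs if r.clade == clade]
        genes = [g for r in clade_bgcs for g in r.genes]
        total = len(genes)
        bg_lookup = bg.set_index("domain")
        for domain in bg_lookup.index:
            with_domain = sum(1 for g in genes if domain in g.domains)
            count_rows.append(
                {
                    "clade": clade, "group": "type3_bgc", "domain": domain,
                    "group_with": with_domain, "group_total": total,
                    "background_with": int(
                        bg_lookup.loc[domain, "background_with"]
                    ),
                    "background_total": int(
                        bg_lookup.loc[domain, "background_total"]
                    ),
                }
            )
    enrichment = enrichment_scan(
        pd.DataFrame(count_rows), config.alpha, config.bonferroni
    )
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)


def _stage_report(config: PipelineConfig, out: Path) -> None:
    render_reports(out)


STAGES: list[tuple[str, list[str], Callable]] = [
    ("simulate",
     ["species_tree.nwk", "gene_trees", "taxonomy.tsv", "gene_table.tsv",
      "domain_hits.tsv", "bgcs.tsv", "background.tsv", "truth.tsv",
      "config.yaml"],
     _stage_simulate),
    ("classify",
     ["classifications.tsv", "loci.tsv", "presence_absence.tsv"],
     _stage_classify),
    ("trees", ["collapsed_trees", "clade_assignments.tsv"], _stage_trees),
    ("reconcile", ["family_events.tsv", "event_summary.tsv"], _stage_reconcile),
    ("hgt", ["hgt_candidates.tsv", "hgt_hits.tsv"], _stage_hgt),
    ("families", ["families.tsv", "distances.tsv"], _stage_families),
    ("occur",
     ["occurrence.tsv", "clade_spread.tsv", "enrichment.tsv"],
     _stage_occur),
    ("report", ["event_table.txt", "report_summary.txt"], _stage_report),
]


def run_pipeline(
    config: PipelineConfig,
    force: bool = False,
    stages: Iterable[str] | None = None,
) -> dict[str, Path]:
    """Run the pipeline stages in order; returns stage output paths.

    A stage runs when forced, explicitly requested, missing any output,
    or when an upstream stage (re)ran; otherwise its files are reused.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = set(stages) if stages is not None else None
    known = {name for name, _, _ in STAGES}
    if requested is not None and requested - known:
        raise ValueError(f"unknown stages: {sorted(requested - known)}")
    upstream_ran = False
    produced: dict[str, Path] = {}
    for name, outputs, fn in STAGES:
        paths = [out / o for o in outputs]
        missing = [p for p in paths if not p.exists()]
        should = (
            force
            or upstream_ran
            or bool(missing)
            or (requested is not None and name in requested)
        )
        if should:
            logger.info(
                "stage %s: running (seed=%s)", name, config.seed
            )
            try:
                fn(config, out)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            upstream_ran = True
        else:
            logger.info("stage %s: outputs present, skipped", name)
        for p in paths:
            produced[p.name] = p
    return produced


def render_reports(out_dir) -> None:
    """Write the human-readable report files from the stage outputs."""
    out = Path(out_dir)
    summary = pd.read_csv(out / "event_summary.tsv", sep="\t")
    # NaN round-trips through TSV; restore None-ness for formatting
    summary = summary.astype(object).where(pd.notna(summary), None)
    for col in summary.columns:
        if col.endswith(("duplications", "transfers", "losses", "n_optimal")):
            summary[col] = [
                int(v) if v is not None else None for v in summary[col]
            ]
    formatted = format_event_table(summary)
    with open(out / "event_table.txt", "w") as fh:
        fh.write(formatted.to_string(index=False) + "\n")

    presence = pd.read_csv(out / "presence_absence.tsv", sep="\t")
    overall = presence[presence["level"] == "overall"].iloc[0]
    events = pd.read_csv(out / "family_events.tsv", sep="\t")
    dtl = events[(events["model"] == "DTL") & events["feasible"]]
    n_transfers = int(dtl["transfers"].sum())
    n_genes = int(
        pd.read_csv(out / "classifications.tsv", sep="\t")["classification"]
        .eq("type3_pks")
        .sum()
    )
    fam_df = pd.read_csv(out / "families.tsv", sep="\t")
    hgt_hits = pd.read_csv(out / "hgt_hits.tsv", sep="\t")
    lines = [
        "pks3evo run summary",
        "===================",
        f"genomes with >=1 type III PKS: {overall['n_with']} of "
        f"{overall['n_with'] + overall['n_without']} "
        f"({overall['percent_with']}%)",
        f"type III PKS genes: {n_genes}",
        f"inferred transfers (DTL, feasible families): {n_transfers}",
        f"minimum HGT frequency: "
        f"{minimum_hgt_frequency(n_transfers, n_genes)}%"
        if n_genes else "minimum HGT frequency: n/a",
        f"gene-cluster families: {fam_df['family_id'].nunique()}",
        f"cross-kingdom best-hit candidates: "
        f"{int((hgt_hits['category'] == 'cross_kingdom').sum())}",
        f"cross-phylum best-hit candidates: "
        f"{int((hgt_hits['category'] == 'cross_phylum').sum())}",
    ]
    with open(out / "report_summary.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
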