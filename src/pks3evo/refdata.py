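"""Published reference values for fungal type III PKS evolution.

Small example datasets distilled from the published kingdom-wide survey
of type III polyketide synthases across 1,193 fungal genomes: the
per-clade reconciliation event counts (DTL model, with the DL-only
alternative in parentheses in the original table), the best-hit table of
PKSs putatively acquired by horizontal transfer, and the headline genome
counts.  They serve as worked-example inputs for the aggregation and
screening code; none of them is recomputable without the original
genome set.
"""

from __future__ import annotations

import pandas as pd

from .hgt import HitRecord

__all__ = [
    "N_GENOMES",
    "N_TYPE3_PKS",
    "N_SPECIES_SINGLE_COPY",
    "N_SPECIES_MULTI_COPY",
    "clade_event_rows",
    "hgt_hit_records",
    "genome_presence_table",
]

#: genomes surveyed / type III PKSs retained by the two-domain signature
N_GENOMES = 1193
N_TYPE3_PKS = 522
#: species with exactly one PKS copy / with two to five copies
N_SPECIES_SINGLE_COPY = 318
N_SPECIES_MULTI_COPY = 89

# per-clade event counts from the reconciliation of the eight fungal
# type III PKS clades against the species tree; DTL columns are None for
# clade 1, where no temporally feasible transfer-aware solution exists
_CLADE_EVENTS = [
    # clade, dtl(dup, trans, loss, n_opt) or None, dl(dup, loss, n_opt)
    ("clade1", None, (34, 126, 1)),
    ("clade2", (0, 1, 3, 2), (1, 10, 1)),
    ("clade3", (15, 0, 25, 1), (15, 25, 1)),
    ("clade4", (4, 0, 31, 1), (4, 31, 1)),
    ("clade5", (3, 1, 23, 1), (5, 30, 1)),
    ("clade6", (6, 4, 38, 16), (8, 72, 1)),
    ("clade7", (0, 5, 3, 16), (1, 41, 1)),
    ("clade8", (3, 26, 46, 1382400), (19, 290, 1)),
]


def clade_event_rows() -> pd.DataFrame:
    """Per-clade, per-model reconciliation rows ready for
    :func:`pks3evo.reconcile.summarize_events`."""
    rows = []
    for clade, dtl, dl in _CLADE_EVENTS:
        if dtl is None:
            rows.append(
                {
                    "clade": clade, "model": "DTL", "duplications": 0,
                    "transfers": 0, "losses": 0, "n_optimal": 1,
                    "feasible": False,
                }
            )
        else:
            dup, trans, loss, n_opt = dtl
            rows.append(
                {
                    "clade": clade, "model": "DTL", "duplications": dup,
                    "transfers": trans, "losses": loss, "n_optimal": n_opt,
                    "feasible": True,
                }
            )
        dup, loss, n_opt = dl
        rows.append(
            {
                "clade": clade, "model": "DL", "duplications": dup,
                "transfers": 0, "losses": loss, "n_optimal": n_opt,
                "feasible": True,
            }
        )
    return pd.DataFrame(rows)


# best blastp hits of the nine fungal type III PKSs flagged as putative
# horizontal acquisitions (eight from Actinobacteria, one fungus-to-fungus)
_HIT_ROWS = [
    ("Ascim1_416225", "Fungi", "Ascomycota", "Pezizomycetes",
     "Type III polyketide synthase Nocardioides lianchengensis",
     "Bacteria", "Actinobacteria", 72.0, 8e-174),
    ("Daces1_533080", "Fungi", "Ascomycota", "Sordariomycetes",
     "Polyketide synthase Mycobacterium gastri",
     "Bacteria", "Actinobacteria", 56.0, 2e-141),
    ("Neora1_900087", "Fungi", "Ascomycota", "Sordariomycetes",
     "Type III polyketide synthase Mycobacterium szulgai",
     "Bacteria", "Actinobacteria", 58.0, 3e-140),
    ("Ilyrob1_539821", "Fungi", "Ascomycota", "Sordariomycetes",
     "Type III polyketide synthase Mycobacterium szulgai",
     "Bacteria", "Actinobacteria", 60.0, 2e-144),
    ("Dacma1_857528", "Fungi", "Ascomycota", "Sordariomycetes",
     "Type III polyketide synthase Mycobacterium szulgai",
     "Bacteria", "Actinobacteria", 58.0, 1e-142),
    ("Aspbrev1_281936", "Fungi", "Ascomycota", "Eurotiomycetes",
     "Type III polyketide synthase Nocardia sp. SYSU K10002",
     "Bacteria", "Actinobacteria", 59.0, 2e-147),
    ("Bombom1_507539", "Fungi", "Ascomycota", "Sordariomycetes",
     "Type III polyketide synthase Nocardia jiangxiensis",
     "Bacteria", "Actinobacteria", 61.0, 2e-131),
    ("Bombar1_591841", "Fungi", "Ascomycota", "Sordariomycetes",
     "Type III polyketide synthase Nocardia yamanashiensis",
     "Bacteria", "Actinobacteria", 54.0, 4e-150),
    ("Olipa1_744902", "Fungi", "Basidiomycota", "Agaricomycetes",
     "Hypothetical protein AK830_g3657 Neonectria ditissima",
     "Fungi", "Ascomycota", 67.0, 1e-300),
]


def hgt_hit_records() -> list[HitRecord]:
    """The nine putative-HGT best-hit rows as :class:`HitRecord` objects.

    The fungus-to-fungus row's e-value is reported as 0.0 in the source
    table; it is stored as 1e-300 to keep a strictly positive value.
    """
    return [
        HitRecord(
            protein_id=p, source_kingdom=sk, source_phylum=sp,
            source_class=sc, hit_description=desc, hit_kingdom=hk,
            hit_phylum=hp, identity=ident, evalue=ev,
        )
        for p, sk, sp, sc, desc, hk, hp, ident, ev in _HIT_ROWS
    ]


def genome_presence_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A synthetic genome-level presence/absence fixture at survey scale.

    Reconstructs taxonomy and classification tables for 1,193 genomes of
    which 407 (318 single-copy + 89 multi-copy) carry at least one type
    III PKS, so the survey-level percentages can be recomputed by
    :func:`pks3evo.trees.class_presence_absence`.  The per-class split is
    synthetic (two placeholder classes per phylum); only the totals are
    anchored to the published counts.
    """
    n_with = N_SPECIES_SINGLE_COPY + N_SPECIES_MULTI_COPY
    rows = []
    genes = []
    for i in range(N_GENOMES):
        genome = f"genome{i + 1:04d}"
        phylum = "Ascomycota" if i % 2 == 0 else "Basidiomycota"
        cls = f"{phylum}_class{(i // 2) % 2 + 1}"
        rows.append(
            {
                "genome_id": genome,
                "kingdom": "Fungi",
                "phylum": phylum,
                "class": cls,
            }
        )
        if i < n_with:
            # multi-copy species carry 2-5 copies; 26 three-copy and 63
            # two-copy genomes bring the gene total to exactly 522
            if i < N_SPECIES_SINGLE_COPY:
                n_copies = 1
            elif i < N_SPECIES_SINGLE_COPY + 26:
                n_copies = 3
            else:
                n_copies = 2
            for k in range(n_copies):
                genes.append(
                    {
                        "gene_id": f"{genome}_pks{k + 1}",
                        "genome_id": genome,
                        "classification": "type3_pks",
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(genes)
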