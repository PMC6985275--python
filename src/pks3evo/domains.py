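"""Pfam-signature classification of PKS proteins and multi-copy loci.

A protein is a type III PKS iff it carries both the chalcone/stilbene
synthase N- and C-terminal domains (PF00195 and PF02797); a protein with
exactly one of the two is treated as a pseudogene / broken gene model and
excluded downstream.  Reducing type I PKSs are recognized by a
ketoreductase (PF08659) or dehydratase (PF14765) domain in the absence of
any non-reducing signature (SAT PF16073 or PT TIGR04532).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "TYPE3_DOMAINS",
    "REDUCING_DOMAINS",
    "NONREDUCING_DOMAINS",
    "DomainHit",
    "GeneRecord",
    "PKSLocus",
    "parse_domain_hits",
    "classify_protein",
    "classify_hits_table",
    "detect_multi_pks_loci",
    "genes_from_gff",
]

TYPE3_DOMAINS = frozenset({"PF00195", "PF02797"})
REDUCING_DOMAINS = frozenset({"PF08659", "PF14765"})
NONREDUCING_DOMAINS = frozenset({"PF16073", "TIGR04532"})


@dataclass(frozen=True)
class DomainHit:
    """One domain hit on a protein (envelope coordinates, 1-based)."""

    protein_id: str
    accession: str
    evalue: float
    score: float
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}/{self.accession}: start > end"
            )
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative e-value")


@dataclass
class GeneRecord:
    """A gene with genomic coordinates (0-based, half-open) and its
    ordered domain content."""

    gene_id: str
    genome_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    domains: list[str] = field(default_factory=list)
    classification: str = "other"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")


def parse_domain_hits(path, evalue_cutoff: float = 1e-5) -> list[DomainHit]:
    """Read a whitespace-delimited domain-hit table.

    Expected columns (a documented subset of HMMER's tabular output):
    ``protein_id  domain_accession  evalue  bitscore  env_start  env_end``.
    Lines starting with ``#`` are comments.  Rows with e-value above the
    cutoff are dropped; the result is grouped by protein (order of first
    appearance) and sorted by envelope start within each protein.
    """
    hits_by_protein: dict[str, list[DomainHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    accession=fields[1],
                    evalue=float(fields[2]),
                    score=float(fields[3]),
                    start=int(fields[4]),
                    end=int(fields[5]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if hit.evalue > evalue_cutoff:
                continue
            hits_by_protein.setdefault(hit.protein_id, []).append(hit)
    out: list[DomainHit] = []
    for protein in hits_by_protein:
        out.extend(sorted(hits_by_protein[protein], key=lambda h: h.start))
    return out


def classify_protein(hits: Iterable[DomainHit | str]) -> str:
    """Classify one protein from its domain content.

    Accepts :class:`DomainHit` objects or bare accession strings; the
    result depends only on the *set* of accessions.  Precedence: the type
    III test first, then the pseudogene/partial test, then the
    non-reducing signature, then the reducing signature, else ``other``.
    """
    accs = {h.accession if isinstance(h, DomainHit) else str(h) for h in hits}
    n_type3 = len(accs & TYPE3_DOMAINS)
    if n_type3 == 2:
        return "type3_pks"
    if n_type3 == 1:
        return "pseudo_partial"
    if accs & NONREDUCING_DOMAINS:
        return "nonreducing_pks_signature"
    if accs & REDUCING_DOMAINS:
        return "reducing_pks"
    return "other"


def classify_hits_table(hits: Iterable[DomainHit]) -> pd.DataFrame:
    """Classify every protein appearing in a hit list.

    Returns a DataFrame with columns protein_id, classification, domains
    (comma-joined, in envelope order).
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    rows = []
    for protein, phits in by_protein.items():
        phits = sorted(phits, key=lambda h: h.start)
        rows.append(
            {
                "protein_id": protein,
                "classification": classify_protein(phits),
                "domains": ",".join(h.accession for h in phits),
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "classification", "domains"])


@dataclass
class PKSLocus:
    """A run of >= 2 type III PKS genes on one scaffold."""

    genome_id: str
    scaffold: str
    genes: list[GeneRecord]
    strand_pattern: str
    divergent_pair: bool

    @property
    def size(self) -> int:
        return len(self.genes)


def detect_multi_pks_loci(
    genes: Iterable[GeneRecord], max_gap_bp: int = 20000
) -> list[PKSLocus]:
    """Group type III PKS genes into multi-copy loci.

    Genes classified ``type3_pks`` on the same scaffold are chained
    whenever the gap between consecutive genes (next start minus previous
    end) is at most ``max_gap_bp``; chains with >= 2 members are reported.
    A locus is flagged ``divergent_pair`` when any adjacent pair is on
    opposite strands.
    """
    type3 = [g for g in genes if g.classification == "type3_pks"]
    by_scaffold: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in type3:
        by_scaffold.setdefault((g.genome_id, g.scaffold), []).append(g)
    loci = []
    for (genome, scaffold), group in sorted(by_scaffold.items()):
        group.sort(key=lambda g: (g.start, g.end))
        chain = [group[0]]
        chains = [chain]
        for g in group[1:]:
            if g.start - chain[-1].end <= max_gap_bp:
                chain.append(g)
            else:
                chain = [g]
                chains.append(chain)
        for chain in chains:
            if len(chain) < 2:
                continue
            strands = "".join(g.strand for g in chain)
            divergent = any(
                a != b for a, b in zip(strands, strands[1:])
            )
            loci.append(
                PKSLocus(genome, scaffold, list(chain), strands, divergent)
            )
    return loci


def genes_from_gff(path, genome_id: str) -> list[GeneRecord]:
    """Minimal GFF3 gene reader (feature type ``gene``).

    GFF3 is 1-based inclusive; coordinates are converted to the package's
    0-based half-open convention.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {lineno}: not GFF3")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"{genome_id}_line{lineno}")
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    scaffold=parts[0],
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    strand=parts[6],
                )
            )
    return records
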