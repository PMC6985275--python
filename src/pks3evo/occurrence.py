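"""Domain-occurrence statistics over gene-cluster families.

For a phylogenetic clade C, the occurrence of a domain d is the sum over
the clade's gene-cluster families n of the fraction of member BGCs that
contain d — each BGC counting d at most once, and domains sitting only on
core (biosynthetic) genes contributing nothing:

    O(C, d) = sum over n in C of |{B in n : d in B}| / |n|

The derived frequency divides by the number of families in the clade, so
0 <= O <= n_families and 0 <= frequency <= 1.  Enrichment of a domain in
a BGC group versus the non-BGC proteome uses the 2x2 chi-square test with
Yates' continuity correction and a one-sided excess rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .bgc import BGCRecord, GeneClusterFamily

__all__ = [
    "OccurrenceTable",
    "occurrence_table",
    "clade_spread",
    "chi2_yates",
    "enrichment_scan",
]


@dataclass
class OccurrenceTable:
    """Per-(clade, domain) occurrence values plus per-clade family counts."""

    table: pd.DataFrame  # columns: clade, domain, occurrence, frequency
    n_families: dict[str, int]

    def value(self, clade: str, domain: str) -> float:
        sub = self.table[
            (self.table["clade"] == clade) & (self.table["domain"] == domain)
        ]
        return float(sub["occurrence"].iloc[0]) if len(sub) else 0.0


def occurrence_table(
    families_by_clade: Mapping[str, Sequence[GeneClusterFamily]],
    bgc_lookup: Mapping[str, BGCRecord],
    exclude_core: bool = True,
) -> OccurrenceTable:
    """Evaluate O(C, d) for every clade and domain.

    ``families_by_clade`` maps clade ids to their gene-cluster families;
    every member BGC id must resolve through ``bgc_lookup`` and belong to
    exactly one family.  With ``exclude_core`` (default), a BGC's domain
    set is taken over non-core genes only, applied *before* the
    once-per-BGC counting.
    """
    seen: dict[str, str] = {}
    rows = []
    n_families: dict[str, int] = {}
    for clade, families in families_by_clade.items():
        n_families[clade] = len(families)
        occ: dict[str, float] = {}
        for family in families:
            size = len(family.members)
            if size == 0:
                raise ValueError(f"family {family.family_id} is empty")
            domain_hits: dict[str, int] = {}
            for bgc_id in family.members:
                if bgc_id in seen:
                    raise ValueError(
                        f"BGC {bgc_id!r} appears in families "
                        f"{seen[bgc_id]!r} and {family.family_id!r}"
                    )
                seen[bgc_id] = family.family_id
                record = bgc_lookup[bgc_id]
                domains = (
                    record.noncore_domain_types()
                    if exclude_core
                    else record.domain_types()
                )
                for d in domains:  # a set: once per BGC by construction
                    domain_hits[d] = domain_hits.get(d, 0) + 1
            for d, k in domain_hits.items():
                occ[d] = occ.get(d, 0.0) + k / size
        for d in sorted(occ):
            rows.append(
                {
                    "clade": clade,
                    "domain": d,
                    "occurrence": occ[d],
                    "frequency": occ[d] / n_families[clade]
                    if n_families[clade]
                    else 0.0,
                }
            )
    table = pd.DataFrame(
        rows, columns=["clade", "domain", "occurrence", "frequency"]
    )
    return OccurrenceTable(table=table, n_families=n_families)


def clade_spread(occurrences: OccurrenceTable) -> pd.DataFrame:
    """Per-domain count of clades with O > 0, plus the maximum occurrence."""
    tbl = occurrences.table
    if tbl.empty:
        return pd.DataFrame(columns=["domain", "n_clades", "max_occurrence"])
    pos = tbl[tbl["occurrence"] > 0]
    out = (
        pos.groupby("domain")
        .agg(n_clades=("clade", "nunique"), max_occurrence=("occurrence", "max"))
        .reset_index()
        .sort_values("domain", ignore_index=True)
    )
    return out


def chi2_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """2x2 chi-square statistic with Yates' continuity correction.

    ``statistic = N * (max(|ad - bc| - N/2, 0))^2 /
    ((a+b)(c+d)(a+c)(b+d))`` with ``N = a+b+c+d``; the p-value comes from
    the chi-square distribution with one degree of freedom.  A zero
    marginal makes the statistic undefined: ``(nan, 1.0)`` is returned by
    convention.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan"), 1.0
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    stat = n * num * num / denom
    p = float(_chi2_dist.sf(stat, df=1))
    return stat, p


def enrichment_scan(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Chi-square (Yates) enrichment of domains in BGC groups.

    ``counts`` needs one row per (clade, group, domain) with columns:
    clade, group, domain, group_with (genes in the group carrying the
    domain), group_total, background_with, background_total — the
    background being the strictly non-BGC proteome.  A domain is flagged
    enriched when p < alpha *and* its proportion in the group exceeds the
    background proportion (excess only; depletion is never flagged).
    ``bonferroni`` divides alpha by the number of tests.
    """
    required = {
        "clade", "group", "domain", "group_with", "group_total",
        "background_with", "background_total",
    }
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    threshold = alpha / len(counts) if (bonferroni and len(counts)) else alpha
    rows = []
    for _, r in counts.iterrows():
        a = int(r["group_with"])
        b = int(r["group_total"]) - a
        c = int(r["background_with"])
        d = int(r["background_total"]) - c
        if min(b, d) < 0:
            raise ValueError(
                f"{r['domain']}: totals smaller than with-domain counts"
            )
        stat, p = chi2_yates(a, b, c, d)
        group_prop = a / (a + b) if a + b else 0.0
        bg_prop = c / (c + d) if c + d else 0.0
        rows.append(
            {
                "clade": r["clade"],
                "group": r["group"],
                "domain": r["domain"],
                "a": a, "b": b, "c": c, "d": d,
                "chi2": stat,
                "p_value": p,
                "enriched": bool(p < threshold and group_prop > bg_prop),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["clade", "group", "domain", "a", "b", "c", "d",
                 "chi2", "p_value", "enriched"],
    )
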