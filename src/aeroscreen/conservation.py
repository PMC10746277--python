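"""Comparative-genomics summaries from a precomputed orthogroup table.

Operates on an Orthogroups.tsv-dialect table (orthogroup id, one column
per species, comma-separated gene lists) plus published essential-gene
lists per comparator species. Reports core-genome membership of the
focal species, its unique genes, and for each focal essential gene how
many comparators carry an essential homolog, binned into tiers:
most (4-7 comparators), some (1-3), none (0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gene_calls import percent

TIER_MOST_MIN = 4


@dataclass
class OrthogroupTable:
    """orthogroup_id -> {species -> [gene ids]}, plus unassigned genes."""

    groups: dict[str, dict[str, list[str]]]
    species: list[str]
    unassigned: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path, unassigned_path=None) -> "OrthogroupTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        species = list(df.columns[1:])
        groups = {}
        for row in df.itertuples(index=False):
            entry = {}
            for i, sp in enumerate(species, start=1):
                cell = row[i].strip()
                if cell:
                    entry[sp] = [g.strip() for g in cell.split(",") if g.strip()]
            groups[row[0]] = entry
        unassigned = {}
        if unassigned_path is not None:
            u = pd.read_csv(unassigned_path, sep="\t", dtype=str).fillna("")
            for sp in u.columns:
                unassigned[sp] = [g for g in u[sp] if g]
        return cls(groups, species, unassigned)

    def genes_of(self, species: str):
        for og, entry in self.groups.items():
            for g in entry.get(species, []):
                yield og, g

    def group_of(self, species: str, gene: str) -> str | None:
        for og, entry in self.groups.items():
            if gene in entry.get(species, []):
                return og
        return None


def core_conserved(
    table: OrthogroupTable,
    comparators: list[str],
    focal: str | None = None,
    count_genes: bool = False,
) -> dict:
    """Core orthogroups (>= 1 gene in every comparator) and focal coverage.

    By default counts orthogroups; ``count_genes=True`` instead counts
    focal genes inside core groups. Coverage percentage is rounded half
    away from zero.
    """
    if not comparators:
        raise ValueError("comparator set must be non-empty")
    unknown = set(comparators) - set(table.species)
    if unknown:
        raise ValueError(f"comparators absent from table: {sorted(unknown)}")
    core = [
        og
        for og, entry in table.groups.items()
        if all(entry.get(sp) for sp in comparators)
    ]
    out = dict(core_orthogroups=core, n_core=len(core))
    if focal is not None:
        with_focal = [og for og in core if table.groups[og].get(focal)]
        if count_genes:
            n_focal = sum(len(table.groups[og].get(focal, [])) for og in core)
        else:
            n_focal = len(with_focal)
        out.update(
            focal_core_orthogroups=with_focal,
            n_focal_core=n_focal,
            percent_focal_core=percent(n_focal, len(core)) if core else 0,
        )
    return out


def unique_genes(table: OrthogroupTable, focal: str, comparators: list[str]) -> set[str]:
    """Focal genes with no homolog in any comparator.

    Focal genes in orthogroups devoid of comparator genes, plus focal
    genes unassigned to any orthogroup.
    """
    if focal not in table.species:
        raise ValueError(f"focal species {focal!r} absent from table")
    out = set()
    for og, entry in table.groups.items():
        focal_genes = entry.get(focal, [])
        if focal_genes and not any(entry.get(sp) for sp in comparators):
            out.update(focal_genes)
    out.update(table.unassigned.get(focal, []))
    return out


def essentiality_tiers(
    table: OrthogroupTable,
    catalog: dict[str, set],
    focal: str,
    focal_essential: list[str],
    comparators: list[str],
    tier_most_min: int = TIER_MOST_MIN,
) -> dict:
    """Essential-homolog sharing tiers for the focal essential gene set.

    For each focal essential gene, counts comparators whose members of
    that gene's orthogroup intersect the comparator's essential set.
    Genes absent from the table count toward tier "none" and are
    flagged. Percentages are integer-rounded half away from zero.
    """
    missing_cat = set(comparators) - set(catalog)
    if missing_cat:
        raise ValueError(f"essentiality catalog missing comparators: {sorted(missing_cat)}")
    per_gene = {}
    flagged = []
    for gene in focal_essential:
        og = table.group_of(focal, gene)
        if og is None:
            per_gene[gene] = 0
            flagged.append(gene)
            continue
        entry = table.groups[og]
        n = sum(
            1
            for sp in comparators
            if any(g in catalog[sp] for g in entry.get(sp, []))
        )
        per_gene[gene] = n
    n_total = len(focal_essential)
    tiers = dict(most=0, some=0, none=0)
    for n in per_gene.values():
        if n >= tier_most_min:
            tiers["most"] += 1
        elif n >= 1:
            tiers["some"] += 1
        else:
            tiers["none"] += 1
    return dict(
        n_essential=n_total,
        per_gene=per_gene,
        tier_counts=tiers,
        tier_percent={
            k: percent(v, n_total) if n_total else 0 for k, v in tiers.items()
        },
        percent_any=percent(tiers["most"] + tiers["some"], n_total) if n_total else 0,
        not_in_table=flagged,
    )
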