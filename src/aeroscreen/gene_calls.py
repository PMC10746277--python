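"""Gene-level aggregation and conditional-essentiality classification.

A gene's fitness score per condition is the median LFC of its targeting
spacers (robust to individual ineffective or off-target guides); its
significance is the Stouffer combination of those spacers' FDR values.
Genes are then classified with inclusive thresholds: generally
essential when median LFC <= -3 and significance <= 0.05 in both
conditions, conditionally essential when that conjunction holds in
exactly one condition, otherwise a fitness defect when median
LFC <= -1 with significance <= 0.05 in one or both conditions, else
non-essential. A separate two-sided sensitivity flag marks genes with
|median LFC| >= 1 and p < 0.05 in exactly one condition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

logger = logging.getLogger(__name__)

CONTROL = "CONTROL"

ESSENTIAL_LFC = -3.0
DEFECT_LFC = -1.0
ALPHA = 0.05
SENSITIVITY_LFC = 1.0

CLASS_LABELS = (
    "generally_essential",
    "conditionally_essential_aerobic",
    "conditionally_essential_anaerobic",
    "fitness_defect_aerobic",
    "fitness_defect_anaerobic",
    "fitness_defect_both",
    "non_essential",
)

_Q_CLAMP = 1e-15


def gene_median_lfc(lfcs) -> float:
    """Exact median of a gene's spacer LFCs (mean of middle two for even n)."""
    lfcs = np.asarray(lfcs, dtype=float)
    if lfcs.size == 0:
        return np.nan
    return float(np.median(lfcs))


def stouffer_combine(qs) -> float:
    """Stouffer combination of a gene's spacer FDR values.

    z_i = Phi^-1(1 - q_i); Z = sum(z_i)/sqrt(k); combined p = 1 - Phi(Z).
    Inputs are clamped to [1e-15, 1 - 1e-15]. One-sided in the
    small-q-is-significant direction and directionless with respect to
    LFC sign; the median-LFC threshold guards against discordant guides.
    """
    qs = np.asarray(qs, dtype=float)
    if qs.size == 0:
        raise ValueError("stouffer_combine requires at least one q value")
    if np.any((qs < 0) | (qs > 1) | ~np.isfinite(qs)):
        raise ValueError("q values must lie in [0, 1]")
    qs = np.clip(qs, _Q_CLAMP, 1.0 - _Q_CLAMP)
    z = ndtri(1.0 - qs)
    Z = z.sum() / np.sqrt(qs.size)
    return float(1.0 - ndtr(Z))


def aggregate_genes(
    spacer_stats: pd.DataFrame,
    library: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene median LFC, Stouffer p, and spacer count for one condition.

    Every targeting gene in the library is reported; genes whose spacers
    are all missing from the stats table get null scores rather than
    being dropped.
    """
    stats = spacer_stats.merge(
        library.loc[library.gene_id != CONTROL, ["spacer_id", "gene_id"]],
        on="spacer_id",
        how="inner",
        suffixes=("_stat", ""),
    )
    if "gene_id_stat" in stats.columns:
        stats = stats.drop(columns=["gene_id_stat"])
    rows = []
    for gid in library.loc[library.gene_id != CONTROL, "gene_id"].unique():
        sub = stats[stats.gene_id == gid]
        if len(sub) == 0:
            rows.append(dict(gene_id=gid, median_lfc=np.nan, stouffer_p=np.nan, n_spacers=0))
            continue
        rows.append(
            dict(
                gene_id=gid,
                median_lfc=gene_median_lfc(sub.lfc),
                stouffer_p=stouffer_combine(sub.q),
                n_spacers=len(sub),
            )
        )
    return pd.DataFrame(rows)


def classify(
    aero_lfc: float,
    aero_p: float,
    anaero_lfc: float,
    anaero_p: float,
    essential_lfc: float = ESSENTIAL_LFC,
    defect_lfc: float = DEFECT_LFC,
    alpha: float = ALPHA,
    conditional_other_fails: str = "conjunction",
) -> str:
    """Classify one gene from both conditions' median LFC and combined p.

    ``conditional_other_fails`` controls the reading of "essential in one
    condition but not the other": "conjunction" (default) demands the
    essential conjunction fail in the other condition; "lfc" demands the
    LFC criterion itself fail there (stricter), else the gene is promoted
    to generally essential.
    """
    if any(np.isnan(v) for v in (aero_lfc, aero_p, anaero_lfc, anaero_p)):
        raise ValueError("both conditions must be scored to classify")

    def essential(lfc, p):
        return lfc <= essential_lfc and p <= alpha

    def defect(lfc, p):
        return lfc <= defect_lfc and p <= alpha

    ess_a, ess_n = essential(aero_lfc, aero_p), essential(anaero_lfc, anaero_p)
    if ess_a and ess_n:
        return "generally_essential"
    if conditional_other_fails == "lfc":
        if ess_a and anaero_lfc <= essential_lfc:
            return "generally_essential"
        if ess_n and aero_lfc <= essential_lfc:
            return "generally_essential"
    if ess_a:
        return "conditionally_essential_aerobic"
    if ess_n:
        return "conditionally_essential_anaerobic"
    def_a, def_n = defect(aero_lfc, aero_p), defect(anaero_lfc, anaero_p)
    if def_a and def_n:
        return "fitness_defect_both"
    if def_a:
        return "fitness_defect_aerobic"
    if def_n:
        return "fitness_defect_anaerobic"
    return "non_essential"


def sensitivity_call(
    aero_lfc: float,
    aero_p: float,
    anaero_lfc: float,
    anaero_p: float,
    sensitivity_lfc: float = SENSITIVITY_LFC,
    alpha: float = ALPHA,
) -> str:
    """Condition-specific sensitivity flag (two-sided on LFC magnitude).

    Flags a condition when |median LFC| >= 1 and p < 0.05 there while the
    other condition fails either criterion; genes qualifying in both (or
    neither) condition get "none".
    """
    hit_a = abs(aero_lfc) >= sensitivity_lfc and aero_p < alpha
    hit_n = abs(anaero_lfc) >= sensitivity_lfc and anaero_p < alpha
    if hit_a and not hit_n:
        return "aerobic_sensitive"
    if hit_n and not hit_a:
        return "anaerobic_sensitive"
    return "none"


def call_genes(
    aero: pd.DataFrame,
    anaero: pd.DataFrame,
    tu_table: pd.DataFrame | None = None,
    **classify_kw,
) -> pd.DataFrame:
    """Join per-condition gene aggregates into the final call table."""
    merged = aero.merge(anaero, on="gene_id", suffixes=("_aerobic", "_anaerobic"))
    labels, flags = [], []
    for row in merged.itertuples(index=False):
        args = (
            row.median_lfc_aerobic,
            row.stouffer_p_aerobic,
            row.median_lfc_anaerobic,
            row.stouffer_p_anaerobic,
        )
        labels.append(classify(*args, **classify_kw))
        flags.append(sensitivity_call(*args))
    merged["class_label"] = labels
    merged["sensitivity_flag"] = flags
    merged["few_spacers"] = (
        merged[["n_spacers_aerobic", "n_spacers_anaerobic"]].min(axis=1) < 4
    )
    if tu_table is not None:
        merged = annotate_tu(merged, tu_table)
    return merged


def annotate_tu(calls: pd.DataFrame, tu_table: pd.DataFrame) -> pd.DataFrame:
    """Attach TU id and ordered co-member list to each gene call.

    TUs must partition genes (a gene in two TUs is an error); genes
    absent from the TU table fall back to singletons with a warning.
    """
    gene_tu: dict[str, str] = {}
    members: dict[str, str] = {}
    for row in tu_table.itertuples(index=False):
        for gid in str(row.members).split(","):
            if gid in gene_tu:
                raise ValueError(f"gene {gid} assigned to multiple TUs")
            gene_tu[gid] = row.tu_id
            members[gid] = row.members
    calls = calls.copy()
    tu_ids, mem = [], []
    for gid in calls.gene_id:
        if gid in gene_tu:
            tu_ids.append(gene_tu[gid])
            mem.append(members[gid])
        else:
            logger.warning("gene %s absent from TU table; singleton fallback", gid)
            tu_ids.append(f"singleton_{gid}")
            mem.append(gid)
    calls["tu_id"] = tu_ids
    calls["tu_members"] = mem
    return calls


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero (the ~N% convention)."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    x = 100.0 * numerator / denominator
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def summarize(calls: pd.DataFrame, total_protein_coding: int | None = None) -> dict:
    """Class counts plus the generally-essential percentage of the genome."""
    n = len(calls)
    counts = {label: int((calls.class_label == label).sum()) for label in CLASS_LABELS}
    total = total_protein_coding if total_protein_coding is not None else n
    summary = dict(
        n_genes=n,
        class_counts=counts,
        n_generally_essential=counts["generally_essential"],
        total_protein_coding=total,
        percent_generally_essential=percent(counts["generally_essential"], total)
        if total
        else 0,
    )
    return summary
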