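"""Consensus transcription units from per-condition transcript predictions.

Predicted transcript isoforms (from any upstream caller) that cover the
same gene set are merged across growth conditions by single-linkage
hierarchical clustering under the pseudo-distance

    d(a, b) = max(len(a), len(b)) - overlap(a, b)   [base pairs]

cut at a cophenetic height of 100 bp; each cluster becomes one TU whose
boundaries are the most extreme member boundaries. Cross-strand and
cross-replicon distances are infinite (never merged). Coordinates are
1-based inclusive throughout; BED I/O converts at the boundary.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_CUTOFF = 100
DEFAULT_OVERLAP_FRAC = 0.5

TRANSCRIPT_COLS = ["replicon", "start", "end", "strand", "source_label"]


def _length(start: int, end: int) -> int:
    return end - start + 1


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def pseudo_distance(a, b) -> float:
    """max(len) - overlap, in bp; +inf across replicons or strands.

    Symmetric, zero iff the intervals are identical; the triangle
    inequality is not guaranteed (it is a pseudo-distance). ``a`` and
    ``b`` are any objects with replicon/start/end/strand attributes or
    keys.
    """

    def get(t, k):
        return t[k] if isinstance(t, dict) else getattr(t, k)

    if get(a, "replicon") != get(b, "replicon") or get(a, "strand") != get(b, "strand"):
        return math.inf
    la = _length(get(a, "start"), get(a, "end"))
    lb = _length(get(b, "start"), get(b, "end"))
    ov = _overlap(get(a, "start"), get(a, "end"), get(b, "start"), get(b, "end"))
    return float(max(la, lb) - ov)


def cluster_transcripts(transcripts: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Single-linkage cluster labels at the given cophenetic cutoff.

    Transcripts must share replicon and strand (grouping is done by the
    caller); returns an integer label per row.
    """
    n = len(transcripts)
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.array([0])
    rows = list(transcripts.itertuples(index=False))
    dm = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        dm[i, j] = dm[j, i] = pseudo_distance(rows[i], rows[j])
    Z = linkage(squareform(dm, checks=False), method="single")
    return fcluster(Z, t=cutoff, criterion="distance") - 1


def covered_genes(
    transcript,
    annotation: pd.DataFrame,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
) -> frozenset:
    """Genes covered by a transcript: same strand/replicon overlap of at
    least ``overlap_frac`` of the gene length (any 1-bp overlap when 0)."""

    def get(t, k):
        return t[k] if isinstance(t, dict) else getattr(t, k)

    rep, strand = get(transcript, "replicon"), get(transcript, "strand")
    ts, te = get(transcript, "start"), get(transcript, "end")
    out = []
    sub = annotation[(annotation.replicon == rep) & (annotation.strand == strand)]
    for g in sub.itertuples(index=False):
        ov = _overlap(ts, te, g.start, g.end)
        glen = _length(g.start, g.end)
        if (overlap_frac <= 0 and ov >= 1) or (overlap_frac > 0 and ov >= overlap_frac * glen):
            out.append(g.gene_id)
    return frozenset(out)


def _group_keys(
    transcripts: pd.DataFrame,
    annotation: pd.DataFrame,
    overlap_frac: float,
    grouping: str,
) -> list:
    keys = [
        (row.replicon, row.strand, covered_genes(row, annotation, overlap_frac))
        for row in transcripts.itertuples(index=False)
    ]
    if grouping == "exact":
        return keys
    if grouping != "containment":
        raise ValueError("grouping must be 'exact' or 'containment'")
    # union-find over distinct keys: merge when one gene set contains the other
    uniq = sorted(set(keys), key=lambda k: (k[0], k[1], sorted(k[2])))
    parent = list(range(len(uniq)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(uniq)), 2):
        (ri, si, gi), (rj, sj, gj) = uniq[i], uniq[j]
        if ri == rj and si == sj and gi and gj and (gi <= gj or gj <= gi):
            parent[find(i)] = find(j)
    canon = {uniq[i]: uniq[find(i)] for i in range(len(uniq))}
    merged = {}
    for k, root in canon.items():
        merged.setdefault(root, set()).update(k[2])
    return [
        (k[0], k[1], frozenset(merged[canon[k]]))
        for k in keys
    ]


def merge_all(
    tables: list[pd.DataFrame],
    annotation: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
    grouping: str = "exact",
) -> pd.DataFrame:
    """Pool transcript tables, group by covered-gene set, cluster, merge.

    Transcripts covering no gene at the threshold are dropped. Output
    TUs carry most-extreme boundaries, member genes in genomic order,
    and the number of supporting transcripts; rows are sorted by
    (replicon, start) and deterministically numbered.
    """
    if not tables:
        raise ValueError("need at least one transcript table")
    pooled = pd.concat(tables, ignore_index=True)
    if len(pooled) == 0:
        return pd.DataFrame(
            columns=["tu_id", "replicon", "start", "end", "strand", "members", "n_transcripts"]
        )
    known = set(annotation.replicon)
    unknown = set(pooled.replicon) - known
    if unknown:
        raise ValueError(f"transcript replicons absent from annotation: {sorted(unknown)}")

    own_genes = [
        covered_genes(row, annotation, overlap_frac)
        for row in pooled.itertuples(index=False)
    ]
    keys = _group_keys(pooled, annotation, overlap_frac, grouping)
    pooled = pooled.assign(_key=keys, _genes=own_genes)
    gene_pos = dict(zip(annotation.gene_id, annotation.start))

    tus = []
    for (rep, strand, genes), grp in pooled.groupby("_key", sort=False):
        if not genes:
            continue
        labels = cluster_transcripts(grp.drop(columns=["_key", "_genes"]), cutoff)
        for lab in np.unique(labels):
            sub = grp[labels == lab]
            # members: genes covered by this cluster's own transcripts
            # (equal to the group key under exact grouping)
            members = frozenset().union(*sub._genes)
            tus.append(
                dict(
                    replicon=rep,
                    start=int(sub.start.min()),
                    end=int(sub.end.max()),
                    strand=strand,
                    members=",".join(sorted(members, key=lambda g: gene_pos[g])),
                    n_transcripts=len(sub),
                )
            )
    out = pd.DataFrame(tus).sort_values(["replicon", "start", "end", "strand"]).reset_index(drop=True)
    out.insert(0, "tu_id", [f"TU{i:04d}" for i in range(len(out))])
    return out
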