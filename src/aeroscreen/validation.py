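"""Self-validation runs: null calibration, ground-truth recovery, oracles.

These functions regenerate synthetic screens from scratch and measure
how well the pipeline recovers known truth; they back both the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import guide_stats
from .counting import count_spacers
from .fixtures import RECOVERY_EFFECTS, null_config, recovery_config
from .gene_calls import CONTROL
from .pipeline import analyze_counts, recovery_metrics
from .simulate import (
    CONDITIONS,
    SimConfig,
    make_effects,
    quick_library,
    revcomp,
    simulate_counts,
)
from .tu_merge import cluster_transcripts, pseudo_distance


def _simulate_quick_screen(config: SimConfig, effects_spec: dict, seed: int):
    rng = np.random.default_rng(seed)
    library = quick_library(config, rng)
    annotation = pd.DataFrame(
        {"gene_id": sorted(set(library.gene_id) - {CONTROL})}
    )
    effects = make_effects(annotation, config, **effects_spec, rng=rng)
    mats = [
        simulate_counts(library, effects, config, cond, None, rng)
        for cond in CONDITIONS
    ]
    return library, effects, mats[0].merge(mats[1])


def null_calibration(n_runs: int = 20, base_seed: int = 0) -> dict:
    """Type-I calibration on all-neutral screens (10,000 spacers each).

    For every run and condition: the fraction of spacers with p < 0.05,
    and the realized false-discovery proportion at q <= 0.05 (on a full
    null every discovery is false, so per-analysis FDP is 1 when BH
    rejects anything and 0 otherwise).
    """
    fracs, fdps = [], []
    for k in range(n_runs):
        seed = base_seed + k
        cfg = null_config(seed)
        library, effects, counts = _simulate_quick_screen(cfg, {}, seed)
        controls = library.loc[library.gene_id == CONTROL, "spacer_id"]
        sf = guide_stats.normalize(counts, control_ids=controls)
        trend = guide_stats.fit_dispersion(counts, sf)
        for cond in CONDITIONS:
            st = guide_stats.test_spacers(counts, sf, trend, cond)
            fracs.append(float((st.p < 0.05).mean()))
            n_rej = int((st.q <= 0.05).sum())
            fdps.append(1.0 if n_rej > 0 else 0.0)
    return dict(
        p_lt_05_fractions=fracs,
        p_lt_05_mean=float(np.mean(fracs)),
        realized_fdp=fdps,
        realized_fdr=float(np.mean(fdps)),
        n_analyses=len(fracs),
    )


def recovery_run(seed: int = 0) -> dict:
    """Mixed-effect screen recovery: 200 genes with planted fitness effects.

    Returns classification sensitivity for the essential classes, the
    false-essential rate among truly neutral genes, and the error of
    gene-level median-LFC estimates against the truth G * s * median(e).
    """
    cfg = recovery_config(seed)
    library, effects, counts = _simulate_quick_screen(cfg, RECOVERY_EFFECTS, seed)
    res = analyze_counts(counts, library)
    met = recovery_metrics(res["calls"], effects)

    med_eff = (
        library[library.gene_id != CONTROL]
        .groupby("gene_id")
        .efficiency.median()
        .rename("median_efficiency")
    )
    merged = res["calls"].merge(effects, on="gene_id").merge(med_eff, on="gene_id")
    errors = []
    for cond, scol in (("aerobic", "s_aerobic"), ("anaerobic", "s_anaerobic")):
        truth = cfg.doublings * merged[scol] * merged.median_efficiency
        errors.append((merged[f"median_lfc_{cond}"] - truth).to_numpy())
    err = np.concatenate(errors)
    affected = np.concatenate(
        [merged.s_aerobic.to_numpy() != 0, merged.s_anaerobic.to_numpy() != 0]
    )
    met.update(
        median_lfc_bias=float(err.mean()),
        median_lfc_mae=float(np.abs(err).mean()),
        median_lfc_mae_affected=float(np.abs(err[affected]).mean()),
        n_genes=int(len(merged)),
    )
    return met


def tu_oracle_check(n_instances: int = 100, max_transcripts: int = 200,
                    cutoff: float = 100.0, seed: int = 0) -> dict:
    """Clustering vs connected components of the d <= cutoff threshold graph.

    Single linkage cut at cophenetic height equals threshold-graph
    components (minimax-path property); verified on random interval
    instances with a union-find oracle independent of scipy.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, max_transcripts + 1))
        starts = rng.integers(1, 20_000, size=n)
        lengths = rng.integers(50, 2_000, size=n)
        ts = pd.DataFrame(
            dict(replicon="chr", start=starts, end=starts + lengths, strand="+",
                 source_label="x")
        )
        labels = cluster_transcripts(ts, cutoff=cutoff)

        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        rows = list(ts.itertuples(index=False))
        for i in range(n):
            for j in range(i + 1, n):
                if pseudo_distance(rows[i], rows[j]) <= cutoff:
                    parent[find(i)] = find(j)
        roots = [find(i) for i in range(n)]
        same_impl = labels[:, None] == labels[None, :]
        roots = np.asarray(roots)
        same_oracle = roots[:, None] == roots[None, :]
        agree += int((same_impl == same_oracle).all())
    return dict(n_instances=n_instances, n_agreeing=agree,
                agreement=agree / n_instances)


def counting_oracle_check(n_reads: int = 10_000, n_spacers: int = 30,
                          seed: int = 0, tmpdir=None) -> dict:
    """Exact k-mer counting vs a naive (read, spacer) substring scan."""
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(seed)
    bases = list("ACGT")
    seqs = set()
    while len(seqs) < n_spacers:
        seqs.add("".join(rng.choice(bases, size=20)))
    library = pd.DataFrame(
        dict(
            spacer_id=[f"sp{i}" for i in range(n_spacers)],
            sequence=sorted(seqs),
            gene_id="gene",
            offset_frac=0.5,
            efficiency=1.0,
        )
    )
    reads = []
    for _ in range(n_reads):
        r = rng.random()
        filler = "".join(rng.choice(bases, size=60))
        if r < 0.6:
            sp = library.sequence.iloc[int(rng.integers(n_spacers))]
            if rng.random() < 0.5:
                sp = revcomp(sp)
            pos = int(rng.integers(0, 41))
            reads.append(filler[:pos] + sp + filler[pos: 40])
        elif r < 0.65:
            i, j = rng.integers(n_spacers, size=2)
            reads.append(library.sequence.iloc[i] + "AC" + library.sequence.iloc[j])
        else:
            reads.append(filler)

    with tempfile.TemporaryDirectory(dir=tmpdir) as td:
        fq = Path(td) / "reads.fastq"
        with open(fq, "w") as fh:
            for i, s in enumerate(reads):
                fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")
        counts, rep = count_spacers(fq, None, library)

    oracle = dict.fromkeys(library.spacer_id, 0)
    pairs = list(zip(library.spacer_id, library.sequence))
    for read in reads:
        rc = revcomp(read)
        hits = {sid for sid, sp in pairs if sp in read or sp in rc}
        if len(hits) == 1:
            oracle[hits.pop()] += 1
    return dict(
        n_reads=n_reads,
        agree=bool(counts.to_dict() == oracle),
        n_counted=rep.n_counted,
        n_ambiguous=rep.n_ambiguous,
        n_no_match=rep.n_no_match,
    )
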