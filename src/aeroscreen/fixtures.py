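"""Seeded miniature datasets for demos, tests, and calibration runs.

Each preset writes a self-contained directory runnable by the pipeline
(or by individual stages) in well under a minute:

- ``tiny``: 20 genes (3 generally essential), 50 controls, counts only.
- ``null``: all-neutral screen of 10,000 spacers for calibration.
- ``recovery``: 200-gene mixed-effect screen (20 generally essential,
  10 aerobic-only, 10 anaerobic-only, 20 fitness-defect genes) used for
  parameter-recovery checks.
- ``tu_demo``: annotation plus per-condition transcript tables with
  condition-specific isoform ends.
- ``conservation_demo``: orthogroup table for a focal species and seven
  comparators with a known essentiality-tier structure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .simulate import (
    CONDITIONS,
    SimConfig,
    build_library,
    make_effects,
    quick_library,
    simulate_counts,
    simulate_genome,
)

PRESETS = ("tiny", "null", "recovery", "tu_demo", "conservation_demo")

RECOVERY_EFFECTS = dict(
    n_general=20, n_aerobic=10, n_anaerobic=10, n_defect=20,
    s_essential=-0.6, s_defect=-0.15,
)


def recovery_config(seed: int = 0) -> SimConfig:
    return SimConfig(
        n_genes=200, guides_per_gene=4, n_controls=1000,
        depth=500.0, dispersion=0.1, n_replicates=2, seed=seed,
    )


def null_config(seed: int = 0, n_spacers: int = 10_000, n_controls: int = 1000) -> SimConfig:
    n_genes = (n_spacers - n_controls) // 4
    return SimConfig(
        n_genes=n_genes, guides_per_gene=4, n_controls=n_controls,
        depth=500.0, dispersion=0.1, n_replicates=2, seed=seed,
    )


def _simulate_to_dir(config: SimConfig, effects_spec: dict, outdir: Path, with_genome: bool):
    rng = np.random.default_rng(config.seed)
    if with_genome:
        annotation, tu_table, genome = simulate_genome(config, rng)
        library = build_library(genome, annotation, config, rng)
        io.write_fasta(genome, outdir / "genome.fasta")
        io.write_gff3(annotation, outdir / "annotation.gff3")
        io.write_tsv(tu_table, outdir / "tu_truth.tsv")
    else:
        library = quick_library(config, rng)
        annotation = pd.DataFrame(
            {"gene_id": sorted(set(library.gene_id) - {"CONTROL"})}
        )
        tu_table = None
    effects = make_effects(annotation, config, **effects_spec, rng=rng)
    mats = [
        simulate_counts(library, effects, config, cond, tu_table, rng)
        for cond in CONDITIONS
    ]
    counts = mats[0].merge(mats[1])
    io.write_tsv(library, outdir / "library.tsv")
    io.write_tsv(effects, outdir / "truth.tsv")
    counts.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    return library, effects, counts


def _tu_demo(outdir: Path, seed: int):
    rng = np.random.default_rng(seed)
    genes = []
    pos = 100
    for i in range(6):
        genes.append(
            dict(gene_id=f"g{i}", replicon="chr", start=pos, end=pos + 899,
                 strand="+" if i < 4 else "-")
        )
        pos += 1000
    annotation = pd.DataFrame(genes)
    tables = []
    for cond in ("aero_exp", "aero_stat", "anaero_exp", "anaero_stat"):
        jitter5 = int(rng.integers(0, 40))
        jitter3 = int(rng.integers(0, 40))
        tables.append(
            pd.DataFrame(
                [
                    # one TU spanning g0-g1, condition-specific ends
                    dict(replicon="chr", start=100 - jitter5, end=2000 + jitter3,
                         strand="+", source_label=cond),
                    # singleton transcript over g2
                    dict(replicon="chr", start=2100, end=3010, strand="+",
                         source_label=cond),
                    # minus-strand TU over g4-g5
                    dict(replicon="chr", start=4100, end=5999, strand="-",
                         source_label=cond),
                ]
            )
        )
    io.write_gff3(annotation, outdir / "annotation.gff3")
    for i, t in enumerate(tables):
        io.write_tsv(t, outdir / f"transcripts_{i}.tsv")
    return annotation, tables


def _conservation_demo(outdir: Path, seed: int):
    """Orthogroup table with a planned tier structure.

    30 focal essential genes: 18 with essential homologs in >= 4 of the 7
    comparators ("most"), 8 in 1-3 ("some"), 4 in none.
    """
    rng = np.random.default_rng(seed)
    comparators = [f"sp{i}" for i in range(1, 8)]
    focal = "focal"
    groups = {}
    essential = {sp: set() for sp in comparators}
    focal_essential = []
    plan = [("most", 18, (4, 7)), ("some", 8, (1, 3)), ("none", 4, (0, 0))]
    og_i = 0
    for tier, n_genes, (lo, hi) in plan:
        for _ in range(n_genes):
            og = f"OG{og_i:05d}"
            gid = f"F{og_i:04d}"
            focal_essential.append(gid)
            n_ess = int(rng.integers(lo, hi + 1))
            ess_sp = list(rng.choice(comparators, size=n_ess, replace=False))
            entry = {focal: [gid]}
            for sp in comparators:
                g = f"{sp}_{og_i:04d}"
                entry[sp] = [g]
                if sp in ess_sp:
                    essential[sp].add(g)
            groups[og] = entry
            og_i += 1
    # some focal-only groups and comparator-only groups for unique/core logic
    for _ in range(5):
        groups[f"OG{og_i:05d}"] = {focal: [f"F{og_i:04d}"]}
        og_i += 1
    for _ in range(10):
        groups[f"OG{og_i:05d}"] = {sp: [f"{sp}_{og_i:04d}"] for sp in comparators}
        og_i += 1

    species = [focal] + comparators
    rows = []
    for og, entry in groups.items():
        rows.append(
            {"Orthogroup": og, **{sp: ", ".join(entry.get(sp, [])) for sp in species}}
        )
    io.write_tsv(pd.DataFrame(rows), outdir / "orthogroups.tsv")
    for sp in comparators:
        (outdir / f"essential_{sp}.txt").write_text(
            "\n".join(sorted(essential[sp])) + "\n"
        )
    (outdir / "focal_essential.txt").write_text("\n".join(focal_essential) + "\n")
    meta = dict(focal=focal, comparators=comparators,
                planned_tiers=dict(most=18, some=8, none=4))
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    return groups, essential, focal_essential


def make_fixture(preset: str, seed: int = 0, outdir=".") -> Path:
    """Write the named preset dataset under ``outdir``; returns the path."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset == "tiny":
        cfg = SimConfig(n_genes=20, n_controls=50, depth=200.0, seed=seed)
        _simulate_to_dir(cfg, dict(n_general=3, s_essential=-0.6), outdir, with_genome=True)
    elif preset == "null":
        _simulate_to_dir(null_config(seed), {}, outdir, with_genome=False)
    elif preset == "recovery":
        _simulate_to_dir(recovery_config(seed), RECOVERY_EFFECTS, outdir, with_genome=False)
    elif preset == "tu_demo":
        _tu_demo(outdir, seed)
    elif preset == "conservation_demo":
        _conservation_demo(outdir, seed)
    return outdir
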