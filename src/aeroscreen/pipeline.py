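"""End-to-end orchestration of the screen analysis.

A single config object carries paths, thresholds, and the seed; stages
are counting (optional, when FASTQ input is supplied), per-condition
spacer statistics, gene-level calls with TU annotation, and the screen
summary. All intermediate tables are written as TSV and every run logs
its seed and a hash of the resolved config so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import gene_calls, guide_stats, io
from .counting import CountMatrix, count_spacers, merge_columns
from .gene_calls import CONTROL
from .simulate import CONDITIONS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "."
    counts: str | None = None
    samples: str | None = None
    library: str | None = None
    fastq: dict[str, list[str]] = field(default_factory=dict)  # sample_id -> [r1, r2]
    tu_table: str | None = None
    truth: str | None = None  # simulator effects table, enables recovery metrics
    essential_lfc: float = -3.0
    defect_lfc: float = -1.0
    alpha: float = 0.05
    sensitivity_lfc: float = 1.0
    pseudocount: float = 0.5
    cutoff_bp: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.cutoff_bp < 0:
            raise ValueError("cutoff_bp must be >= 0")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def analyze_counts(
    counts: CountMatrix,
    library: pd.DataFrame,
    tu_table: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Counts -> per-spacer stats per condition -> gene calls -> summary."""
    config = config or PipelineConfig()
    controls = library.loc[library.gene_id == CONTROL, "spacer_id"]
    size_factors = guide_stats.normalize(counts, control_ids=controls)
    trend = guide_stats.fit_dispersion(counts, size_factors)

    stats = {}
    aggregates = {}
    for cond in CONDITIONS:
        stats[cond] = guide_stats.test_spacers(
            counts, size_factors, trend, cond, library=library,
            pseudocount=config.pseudocount,
        )
        aggregates[cond] = gene_calls.aggregate_genes(stats[cond], library)

    calls = gene_calls.call_genes(
        aggregates["aerobic"],
        aggregates["anaerobic"],
        tu_table=tu_table,
        essential_lfc=config.essential_lfc,
        defect_lfc=config.defect_lfc,
        alpha=config.alpha,
    )
    summary = gene_calls.summarize(calls)
    return dict(
        size_factors=size_factors,
        trend=trend,
        spacer_stats=stats,
        calls=calls,
        summary=summary,
    )


def recovery_metrics(calls: pd.DataFrame, effects: pd.DataFrame) -> dict:
    """Compare classifications against simulator ground truth."""
    truth_to_call = {
        "generally_essential": "generally_essential",
        "aerobic_essential": "conditionally_essential_aerobic",
        "anaerobic_essential": "conditionally_essential_anaerobic",
    }
    merged = calls.merge(effects, on="gene_id", how="inner")
    ess = merged[merged.class_label_y.isin(truth_to_call)]
    n_correct = sum(
        row.class_label_x == truth_to_call[row.class_label_y]
        for row in ess.itertuples(index=False)
    )
    neutral = merged[merged.class_label_y == "neutral"]
    essential_calls = {
        "generally_essential",
        "conditionally_essential_aerobic",
        "conditionally_essential_anaerobic",
    }
    n_false = int(neutral.class_label_x.isin(essential_calls).sum())
    return dict(
        n_true_essential=len(ess),
        n_recovered=int(n_correct),
        sensitivity=n_correct / len(ess) if len(ess) else float("nan"),
        n_neutral=len(neutral),
        n_false_essential=n_false,
        false_essential_rate=n_false / len(neutral) if len(neutral) else float("nan"),
    )


def run_screen(config: PipelineConfig) -> dict:
    """Execute the pipeline from files per the config; returns results."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run_screen seed=%s config=%s", config.seed, config.digest())

    stage = "inputs"
    try:
        if config.library is None:
            raise ValueError("a spacer library TSV is required")
        library = io.read_tsv(config.library)

        if config.fastq:
            stage = "counting"
            samples = io.read_tsv(config.samples)
            columns = {}
            for sid, pair in config.fastq.items():
                col, rep = count_spacers(pair[0], pair[1] if len(pair) > 1 else None, library)
                columns[sid] = col
                logger.info("counted %s: %s", sid, rep.as_dict())
            counts = merge_columns(columns, samples)
        elif config.counts:
            counts = CountMatrix.from_tsv(config.counts, config.samples)
        else:
            raise ValueError("either FASTQ inputs or a counts TSV is required")

        tu_table = io.read_tsv(config.tu_table) if config.tu_table else None

        stage = "statistics"
        res = analyze_counts(counts, library, tu_table, config)

        stage = "outputs"
        counts.to_tsv(out / "counts.tsv", out / "samples.tsv")
        for cond, df in res["spacer_stats"].items():
            io.write_tsv(df, out / f"spacer_stats_{cond}.tsv")
        io.write_tsv(res["calls"], out / "gene_calls.tsv")
        res["size_factors"].to_csv(out / "size_factors.tsv", sep="\t")
        with open(out / "summary.json", "w") as fh:
            json.dump(res["summary"], fh, indent=2)

        if config.truth:
            stage = "recovery"
            effects = io.read_tsv(config.truth)
            res["recovery"] = recovery_metrics(res["calls"], effects)
            with open(out / "recovery.json", "w") as fh:
                json.dump(res["recovery"], fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    logger.info("run_screen finished in %.1fs", time.time() - t0)
    return res
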