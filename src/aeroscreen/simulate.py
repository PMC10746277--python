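"""Synthetic CRISPRi screen generator.

Produces toy genomes with operon (transcription-unit) structure, spacer
libraries with per-guide knockdown efficiencies, and negative-binomial
screen count matrices with known per-gene fitness effects, so that every
downstream stage of the pipeline can be tested against ground truth.

The selection model is deliberately simple: a gene's fitness effect is a
per-doubling log2 selection coefficient ``s`` (negative = deleterious),
so that over ``G`` population doublings a spacer with knockdown
efficiency ``e`` has expected log2 fold change ``G * s * e`` relative to
a neutral library. CRISPRi polarity (full knockdown of downstream genes
in the same TU, attenuated "reverse-polar" knockdown of upstream genes)
can be switched on to study its confounding effect on gene-level calls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import CountMatrix

CONTROL = "CONTROL"
CONDITIONS = ("aerobic", "anaerobic")
SPACER_LEN = 20

# fixed amplicon flanks for read emission (arbitrary vector sequence)
FLANK5 = "ACACCGTCTCAAGGACGAAACACCG"
FLANK3 = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGC"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Parameters of a simulated screen.

    Defaults mirror the screen design this pipeline targets: 4 guides per
    gene, 1,000 non-targeting controls, ~10 doublings of selection, and
    guide efficiencies drawn from Beta(8, 2) (mean 0.8; the efficiency
    spread of full-complement sgRNAs is not known precisely and is
    exposed as a tunable).
    """

    n_genes: int = 200
    genes_per_tu_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.25, 3: 0.15, 4: 0.10}
    )
    guides_per_gene: int = 4
    n_controls: int = 1000
    doublings: float = 10.0
    depth: float = 500.0
    dispersion: float = 0.1
    efficiency_alpha: float = 8.0
    efficiency_beta: float = 2.0
    n_replicates: int = 2
    gene_length: int = 600
    intergenic_gap: tuple[int, int] = (60, 200)
    intra_tu_gap: tuple[int, int] = (3, 30)
    polar: bool = False
    reverse_polar_5p: float = 0.5
    reverse_polar_3p: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("reverse_polar_5p", "reverse_polar_3p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = sum(self.genes_per_tu_dist.values())
        if total <= 0 or any(v < 0 for v in self.genes_per_tu_dist.values()):
            raise ValueError("genes_per_tu_dist must be a non-negative distribution")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _rng(config_or_seed) -> np.random.Generator:
    if isinstance(config_or_seed, np.random.Generator):
        return config_or_seed
    return np.random.default_rng(config_or_seed)


def nb_sample(rng: np.random.Generator, mean, phi: float) -> np.ndarray:
    """NB draw with variance mu + phi*mu^2; Poisson limit as phi -> 0."""
    mean = np.asarray(mean, dtype=float)
    if phi < 1e-9:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_genome(config: SimConfig, rng=None):
    """Generate a random genome with genes grouped into operons.

    Returns ``(annotation, tu_table, genome)`` where annotation is a
    DataFrame of 1-based inclusive stranded gene intervals, tu_table the
    ground-truth transcription units (members listed in transcription
    order), and genome the chromosome sequence.

    Raises ValueError when the configuration cannot host the requested
    number of PAM-adjacent spacers per gene.
    """
    rng = _rng(config.seed if rng is None else rng)
    if config.gene_length < SPACER_LEN + 3:
        raise ValueError(
            f"gene_length={config.gene_length} too short for {SPACER_LEN}-nt "
            "PAM-adjacent spacers"
        )

    sizes = np.array(sorted(config.genes_per_tu_dist), dtype=int)
    probs = np.array([config.genes_per_tu_dist[s] for s in sizes], dtype=float)
    probs /= probs.sum()

    tu_sizes: list[int] = []
    remaining = config.n_genes
    while remaining > 0:
        k = int(rng.choice(sizes, p=probs))
        k = min(k, remaining)
        tu_sizes.append(k)
        remaining -= k

    bases = np.array(list("ACGT"))
    chunks: list[str] = []
    pos = 0  # 0-based cursor
    genes = []
    tus = []
    gi = 0
    for ti, k in enumerate(tu_sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(*config.intergenic_gap))
        chunks.append("".join(rng.choice(bases, size=gap)))
        pos += gap
        members = []
        for j in range(k):
            if j > 0:
                g = int(rng.integers(*config.intra_tu_gap))
                chunks.append("".join(rng.choice(bases, size=g)))
                pos += g
            gid = f"gene{gi:04d}"
            gi += 1
            chunks.append("".join(rng.choice(bases, size=config.gene_length)))
            genes.append(
                dict(
                    gene_id=gid,
                    replicon="chr",
                    start=pos + 1,
                    end=pos + config.gene_length,
                    strand=strand,
                    tu_id=f"TU{ti:04d}",
                )
            )
            members.append(gid)
            pos += config.gene_length
        if strand == "-":
            members = members[::-1]  # transcription order
        tus.append(
            dict(
                tu_id=f"TU{ti:04d}",
                replicon="chr",
                start=genes[gi - k]["start"],
                end=genes[gi - 1]["end"],
                strand=strand,
                members=",".join(members),
            )
        )
    chunks.append("".join(rng.choice(bases, size=int(rng.integers(*config.intergenic_gap)))))
    genome = "".join(chunks)
    annotation = pd.DataFrame(genes)
    tu_table = pd.DataFrame(tus)

    for _, g in annotation.iterrows():
        n_sites = len(_candidate_spacers(genome, int(g.start), int(g.end)))
        if n_sites < config.guides_per_gene:
            raise ValueError(
                f"{g.gene_id}: only {n_sites} PAM-adjacent spacers available, "
                f"{config.guides_per_gene} requested (gene too short?)"
            )
    return annotation, tu_table, genome


def _candidate_spacers(genome: str, start: int, end: int) -> list[tuple[str, float]]:
    """PAM-adjacent 20-mers fully inside the gene body [start, end] (1-based).

    Simplified SpCas9 enumeration: a spacer is the 20 nt 5' of an NGG PAM
    on either strand; no further design rules are applied.
    """
    lo, hi = start - 1, end  # 0-based half-open gene body
    length = hi - lo
    out = []
    region = genome[lo:hi]
    for i in range(len(region) - 1):
        # + strand: spacer .. N GG ; spacer occupies [i-21-? ...]
        if region[i : i + 2] == "GG" and i - 21 >= 0:
            sp = region[i - 21 : i - 1]
            out.append((sp, (i - 11) / length))
        # - strand PAM is CC on the forward sequence; spacer 3' of it
        if region[i : i + 2] == "CC" and i + 23 <= len(region):
            sp = revcomp(region[i + 3 : i + 23])
            out.append((sp, (i + 13) / length))
    return out


def build_library(genome: str, annotation: pd.DataFrame, config: SimConfig, rng=None) -> pd.DataFrame:
    """Design the spacer library: targeting guides plus non-targeting controls.

    Targeting guides are unique PAM-adjacent 20-mers spread across each
    gene body; controls are random 20-mers verified absent from the
    genome on both strands (bounded rejection sampling). Control records
    carry gene_id = "CONTROL", efficiency 0.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    seen: set[str] = set()
    records = []
    for _, g in annotation.iterrows():
        cands = [
            (sp, off)
            for sp, off in _candidate_spacers(genome, int(g.start), int(g.end))
            if sp not in seen
        ]
        if len(cands) < config.guides_per_gene:
            raise ValueError(f"{g.gene_id}: not enough unique PAM-adjacent spacers")
        cands.sort(key=lambda t: t[1])
        idx = np.linspace(0, len(cands) - 1, config.guides_per_gene).round().astype(int)
        idx = np.unique(idx)
        # linspace rounding can collide for tiny candidate pools; backfill
        extra = [i for i in range(len(cands)) if i not in set(idx)]
        while len(idx) < config.guides_per_gene:
            idx = np.append(idx, extra.pop(0))
        for j, i in enumerate(sorted(idx[: config.guides_per_gene])):
            sp, off = cands[i]
            seen.add(sp)
            records.append(
                dict(
                    spacer_id=f"{g.gene_id}_sp{j}",
                    sequence=sp,
                    gene_id=g.gene_id,
                    offset_frac=round(min(max(off, 0.0), 1.0), 4),
                    efficiency=float(rng.beta(config.efficiency_alpha, config.efficiency_beta)),
                )
            )

    fwd, rev = genome, revcomp(genome)
    bases = np.array(list("ACGT"))
    n_ctrl = 0
    tries = 0
    while n_ctrl < config.n_controls:
        tries += 1
        if tries > 1_000_000:
            raise RuntimeError("could not find non-genomic control sequences")
        sp = "".join(rng.choice(bases, size=SPACER_LEN))
        if sp in seen or sp in fwd or sp in rev:
            continue
        seen.add(sp)
        records.append(
            dict(
                spacer_id=f"ctrl{n_ctrl:04d}",
                sequence=sp,
                gene_id=CONTROL,
                offset_frac=np.nan,
                efficiency=0.0,
            )
        )
        n_ctrl += 1
    return pd.DataFrame(records)


def quick_library(config: SimConfig, rng=None) -> pd.DataFrame:
    """Library records without a genome (for count-level simulations).

    Spacer sequences are random 20-mers (uniqueness enforced); offsets
    are uniform on [0, 1]. Use build_library when reads or polar effects
    anchored to a real layout are needed.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    bases = np.array(list("ACGT"))
    seen: set[str] = set()

    def fresh_seq() -> str:
        while True:
            sp = "".join(rng.choice(bases, size=SPACER_LEN))
            if sp not in seen:
                seen.add(sp)
                return sp

    records = []
    for gi in range(config.n_genes):
        for j in range(config.guides_per_gene):
            records.append(
                dict(
                    spacer_id=f"gene{gi:04d}_sp{j}",
                    sequence=fresh_seq(),
                    gene_id=f"gene{gi:04d}",
                    offset_frac=float(rng.uniform()),
                    efficiency=float(rng.beta(config.efficiency_alpha, config.efficiency_beta)),
                )
            )
    for k in range(config.n_controls):
        records.append(
            dict(
                spacer_id=f"ctrl{k:04d}",
                sequence=fresh_seq(),
                gene_id=CONTROL,
                offset_frac=np.nan,
                efficiency=0.0,
            )
        )
    return pd.DataFrame(records)


def make_effects(
    annotation: pd.DataFrame,
    config: SimConfig,
    n_general: int = 0,
    n_aerobic: int = 0,
    n_anaerobic: int = 0,
    n_defect: int = 0,
    s_essential: float = -0.6,
    s_defect: float = -0.15,
    rng=None,
) -> pd.DataFrame:
    """Assign ground-truth per-doubling selection coefficients to genes.

    Effect classes are drawn without replacement in annotation order
    after a seeded shuffle; remaining genes are neutral. With G = 10
    doublings, s = -0.6 gives a true full-knockdown LFC of -6 (essential
    scale) and s = -0.15 gives -1.5 (fitness defect scale).
    """
    rng = _rng(config.seed + 2 if rng is None else rng)
    gene_ids = list(annotation.gene_id)
    need = n_general + n_aerobic + n_anaerobic + n_defect
    if need > len(gene_ids):
        raise ValueError("more effect genes requested than genes available")
    order = list(rng.permutation(gene_ids))
    rows = []
    pick = lambda n: [order.pop() for _ in range(n)]
    for gid in pick(n_general):
        rows.append((gid, s_essential, s_essential, "generally_essential"))
    for gid in pick(n_aerobic):
        rows.append((gid, s_essential, 0.0, "aerobic_essential"))
    for gid in pick(n_anaerobic):
        rows.append((gid, 0.0, s_essential, "anaerobic_essential"))
    for gid in pick(n_defect):
        rows.append((gid, s_defect, s_defect, "fitness_defect"))
    for gid in order:
        rows.append((gid, 0.0, 0.0, "neutral"))
    eff = pd.DataFrame(rows, columns=["gene_id", "s_aerobic", "s_anaerobic", "class_label"])
    for cls, col in [("aerobic_essential", "s_aerobic"), ("anaerobic_essential", "s_anaerobic")]:
        sel = eff.class_label.isin([cls, "generally_essential"])
        if sel.any() and (config.doublings * eff.loc[sel, col].abs() < 3).any():
            raise ValueError("essential-class |G*s| must be >= 3")
    return eff


def _spacer_fitness(
    library: pd.DataFrame,
    effects: pd.DataFrame,
    config: SimConfig,
    condition: str,
    tu_table: pd.DataFrame | None,
) -> np.ndarray:
    """Per-spacer effective selection coefficient (per doubling, log2)."""
    scol = {"aerobic": "s_aerobic", "anaerobic": "s_anaerobic"}[condition]
    s_map = dict(zip(effects.gene_id, effects[scol]))
    targeted = library.gene_id[library.gene_id != CONTROL]
    missing = set(targeted) - set(s_map)
    if missing:
        raise ValueError(f"missing TrueEffect for targeted genes: {sorted(missing)[:5]}")

    down_up: dict[str, tuple[float, float]] = {}
    if config.polar:
        if tu_table is None:
            raise ValueError("polar simulation requires the TU truth table")
        for _, tu in tu_table.iterrows():
            members = tu.members.split(",")
            for i, gid in enumerate(members):
                down = sum(s_map.get(m, 0.0) for m in members[i + 1 :])
                up = sum(s_map.get(m, 0.0) for m in members[:i])
                down_up[gid] = (down, up)

    s_eff = np.zeros(len(library))
    for i, row in enumerate(library.itertuples(index=False)):
        if row.gene_id == CONTROL:
            continue
        s = s_map[row.gene_id]
        if config.polar:
            down, up = down_up.get(row.gene_id, (0.0, 0.0))
            att = config.reverse_polar_5p + (
                config.reverse_polar_3p - config.reverse_polar_5p
            ) * float(row.offset_frac)
            s = s + down + att * up
        s_eff[i] = s * float(row.efficiency)
    return s_eff


def simulate_counts(
    library: pd.DataFrame,
    effects: pd.DataFrame,
    config: SimConfig,
    condition: str,
    tu_table: pd.DataFrame | None = None,
    rng=None,
) -> CountMatrix:
    """Simulate Ti/Tf replicate counts for one condition.

    Ti counts are NB(depth, phi) per spacer. Tf expected abundance
    multiplies the (uniform) initial abundance by 2^(G*s_g*e_i) (plus
    polar contributions when enabled), is renormalized so the sequenced
    library size matches Ti (fixed-depth conditioning), then NB-sampled.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = _rng(config.seed + 3 if rng is None else rng)
    n = len(library)
    s_eff = _spacer_fitness(library, effects, config, condition, tu_table)
    w = np.exp2(config.doublings * s_eff)
    tf_mean = config.depth * n * (w / w.sum())

    cols = {}
    samples = []
    for tp, mean in (("Ti", np.full(n, config.depth)), ("Tf", tf_mean)):
        for r in range(1, config.n_replicates + 1):
            sid = f"{condition}_{tp}_r{r}"
            cols[sid] = nb_sample(rng, mean, config.dispersion)
            samples.append(dict(sample_id=sid, condition=condition, timepoint=tp, replicate=r))
    counts = pd.DataFrame(cols, index=pd.Index(library.spacer_id, name="spacer_id"))
    return CountMatrix(counts, pd.DataFrame(samples))


def simulate_screen(
    config: SimConfig,
    effects_spec: dict | None = None,
):
    """Convenience wrapper: genome -> library -> effects -> both-condition counts.

    Returns (annotation, tu_table, genome, library, effects, CountMatrix).
    """
    master = np.random.default_rng(config.seed)
    annotation, tu_table, genome = simulate_genome(config, master)
    library = build_library(genome, annotation, config, master)
    effects = make_effects(annotation, config, **(effects_spec or {}), rng=master)
    mats = [
        simulate_counts(library, effects, config, cond, tu_table, master)
        for cond in CONDITIONS
    ]
    counts = mats[0].merge(mats[1])
    return annotation, tu_table, genome, library, effects, counts


def emit_fastq(
    counts: pd.Series,
    library: pd.DataFrame,
    fastq1,
    fastq2,
    read_length: int = 100,
    seed: int = 0,
) -> int:
    """Write one sample's counts as paired amplicon reads.

    Each spacer yields exactly ``count`` read pairs; read 1 carries the
    spacer verbatim between fixed amplicon flanks, read 2 is the reverse
    complement of the amplicon. Returns the number of pairs written.
    """
    if read_length < SPACER_LEN + len(FLANK5):
        raise ValueError("read_length too short to contain flank + spacer")
    seqs = dict(zip(library.spacer_id, library.sequence))
    n_pairs = 0
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for sid, c in counts.items():
            c = int(c)
            if c == 0:
                continue
            amplicon = FLANK5 + seqs[sid] + FLANK3
            r1 = amplicon[:read_length]
            r2 = revcomp(amplicon)[:read_length]
            q1 = "I" * len(r1)
            q2 = "I" * len(r2)
            for k in range(c):
                name = f"{sid}:{k}"
                f1.write(f"@{name}/1\n{r1}\n+\n{q1}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{q2}\n")
                n_pairs += 1
    return n_pairs
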