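# Methods

This note records the models implemented by `aeroscreen`, the reasoning
behind parameter defaults and numerical choices, and what the synthetic
data generator does and does not emulate.

## Screen model and simulator

The simulator encodes the fitness model the analysis assumes. Each gene
carries a per-doubling log₂ selection coefficient `s` per condition
(`s ≤ 0` deleterious, `s = 0` neutral). A spacer with knockdown efficiency
`e ∈ [0,1]` targeting that gene changes relative abundance by `2^(G·s·e)`
over `G` population doublings, so its expected log₂ fold change on a
neutral background is simply `G·s·e`. Defining selection directly on the
log₂-abundance-per-doubling scale avoids committing to a growth-rate model
that the screen itself cannot identify. Defaults are the study conditions:
`G = 10` doublings of exponential selection, 4 targeting spacers per gene,
1,000 non-targeting control spacers, 2 replicates per timepoint, mean
initial depth 500 reads/spacer.

Counts are negative binomial with Var = μ + φμ² and constant simulator
dispersion φ = 0.1, a typical replicate-level overdispersion for pooled
amplicon screens (the estimator, not the simulator, handles mean trends).
The final-timepoint library is renormalized to the initial sequencing
depth before sampling, mimicking fixed sequencing depth per sample
(multinomial conditioning approximated by rescaling means).

Guide efficiencies are Beta(8, 2) (mean 0.8). The efficiency spread of
fully complementary sgRNAs is not precisely known for this system; Beta(8,2)
encodes "mostly strong knockdown with an occasional weak guide" and is
exposed as a tunable. One consequence worth remembering when interpreting
recovery results: a gene's median spacer LFC estimates `G·s·median(e)`, not
`G·s`, so planted essentials at `G·s = −6` yield median LFCs near −4.9.

CRISPRi polarity is off by default. When enabled, a spacer inherits the
full selection coefficient of genes downstream of its target within the
same transcription unit, and an attenuated ("reverse-polar") fraction of
upstream genes' coefficients, interpolated linearly between
`reverse_polar_5p` (offset 0, default 0.5) and `reverse_polar_3p`
(offset 1, default 0.15). The defaults are loosely motivated by reporter
measurements in this organism (≈5.4-fold upstream knockdown when targeting
the 5′ end of the downstream gene, ≈1.8-fold at the 3′ end) but are
parameters, not asserted truth.

The genome generator places non-overlapping, same-strand gene runs
(operons) with TU sizes drawn from a configurable distribution, and designs
spacers by simplified PAM-adjacent enumeration: any 20-mer 5′ of an NGG on
either strand, fully inside the gene body, spread evenly along the gene.
Controls are random 20-mers rejection-sampled (bounded at 10⁶ tries) until
absent from both genome strands. Read emission places each spacer verbatim
between fixed amplicon flanks, so the counting stage can be tested by exact
round trip.

**Not emulated:** sequencing error, PCR jackpotting, positional efficiency
trends, chromosomal polyploidy, mismatch-guide (titration) sublibraries,
batch effects between experiment days. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the assumed NB
model, not robustness to these artifacts of real data.

## Normalization

Size factors are median-of-ratios (reference = per-spacer geometric mean
across samples), rescaled to geometric mean 1. When at least 50
non-targeting controls have nonzero median counts, only controls enter the
median: heavy depletion of essential-gene spacers biases whole-library
scaling toward apparent enrichment of everything else, while the controls
are fitness-neutral by construction. Otherwise the estimator falls back to
all spacers.

## Dispersion estimation

φ(μ) is fitted from initial-timepoint replicates (Tf replicates are
excluded: selection inflates their between-replicate variance for true
hits). Within each condition's Ti group the method-of-moments estimate is
pooled into ≥20 mean-ordered, equal-occupancy bins. The naive per-spacer
estimator `(v − m̂)/m̂²` is biased downward by roughly `(1/μ + φ)/r` at `r`
replicates because `E[m̂²] = μ² + Var(m̂)`; each bin instead solves the
bias-corrected moment equation

    φ_bin = Σ(v − m̂) / Σ(m̂² − v/r),

floored at zero, which recovers simulated φ = 0.1 to within 1% where the
naive estimator is ~5% low at r = 2. Bin values are smoothed by decreasing
isotonic regression (count dispersions shrink with abundance; monotonicity
also regularizes sparse bins) and evaluated by linear interpolation with
clamped extrapolation. With a single replicate the fit refuses and asks for
an explicit constant trend.

## Per-spacer test

For each condition, replicates are averaged on the normalized scale and

    lfc = log2((m̂_Tf + c)/(m̂_Ti + c)),  c = 0.5.

The pseudocount keeps the statistic finite at zero counts; spacers with
zeros at both timepoints are reported as lfc = 0, p = 1 and flagged
low-count rather than dropped. The standard error propagates the NB
variance of each group mean, Var(m̂) = (1/r²)·Σⱼ(μ/sⱼ + φ(μ)μ²), through
the log ratio (delta method), giving a Wald z = lfc/se with two-sided
normal p-values — the same quasi-NB modeling family as standard count-based
screen analyses, fully specified here and validated by calibration tests
rather than by matching any package's internals.

The normal approximation to the log-ratio statistic is accurate in the
bulk (measured null p < 0.05 fraction ≈ 0.053 at depth 500, 2 replicates)
but anti-conservative by several-fold beyond |z| ≈ 4.5, which matters
exactly where Benjamini–Hochberg thresholds land on a 10⁴-spacer screen.
Wald p-values below 10⁻³ are therefore recomputed with an exact conditional
NB test: replicate sums are NB(r/φ) with a common per-replicate mean under
the null, and the p-value doubles the smaller conditional tail of the Tf
sum given the total (binomial in the Poisson limit; counts are
size-factor-adjusted before summing; enumeration is skipped above a total
of 2×10⁵ where the normal tail is accurate and the cost would be large).
q-values are Benjamini–Hochberg within condition across all spacers.

Replication structure is treated as exchangeable within condition; day or
batch covariates are out of scope.

## Gene-level calls

Median spacer LFC (exact median; mean of middle two for even n) and
Stouffer combination of the spacers' FDR values: zᵢ = Φ⁻¹(1−qᵢ) with q
clamped to [10⁻¹⁵, 1−10⁻¹⁵], Z = Σzᵢ/√k, combined p = 1 − Φ(Z). The
combination is one-sided in the "small q" direction and blind to LFC sign;
a gene with discordant-sign guides can be significant, which the median-LFC
threshold then filters. All targeting spacers enter the median, including
low-count ones; genes with fewer than 4 usable spacers are called but
flagged.

Thresholds are inclusive: essential means median LFC ≤ −3 and p ≤ 0.05;
fitness defect means median LFC ≤ −1 and p ≤ 0.05. "Conditionally
essential" requires the essential conjunction to hold in exactly one
condition; whether the *other* condition must fail the whole conjunction or
only the LFC criterion is genuinely ambiguous, so the conjunction-fails
reading is the default and `conditional_other_fails="lfc"` selects the
stricter alternative (which promotes borderline genes to generally
essential). The sensitivity flag (|median LFC| ≥ 1, p < 0.05 in exactly one
condition) is two-sided on purpose — enrichment qualifies.

Displayed percentages round half away from zero, matching the "~N%"
convention of screen reporting.

## Transcription-unit merging

The pseudo-distance d(a,b) = max(len a, len b) − overlap(a,b) is symmetric
with d(a,a) = 0 but does not satisfy the triangle inequality; it penalizes
both length mismatch and lack of overlap in base pairs. Transcripts are
first grouped by (replicon, strand, covered-gene set) — a gene is covered
when the same-strand overlap is at least half the gene length (threshold
exposed; "covered" is otherwise underdetermined) — and each group is
clustered by single linkage with the dendrogram cut at a cophenetic height
of 100 bp. For single linkage that cut equals the connected components of
the d ≤ 100 threshold graph (minimax-path property), which the test suite
verifies against an independent union-find oracle; ties and chaining need
no special handling under this formulation. Merged TUs take the most
extreme member boundaries. Transcript tables from all growth conditions are
pooled before grouping, so condition-specific isoform ends merge into one
consensus TU; gene-set grouping precedes clustering, so overlapping
isoforms covering different gene sets never merge. Cross-strand and
cross-replicon distances are infinite — merging them would be biologically
incoherent. Coordinates are 1-based inclusive internally; BED6 input is
converted at the boundary. Exact gene-set equality is the default grouping;
a containment mode unions nested gene sets before clustering.

## Phenotype models

Growth-curve fitness uses the empirical trapezoidal AUC after subtracting
the curve's initial OD (floored at zero), so inoculum offsets and lag-phase
baselines do not inflate the area; the exact baseline convention of other
AUC implementations is not standardized, so it is fixed and documented
here. Relative fitness doubly normalizes: to the strain's own vehicle-only
curve, then to the non-targeting control strain's ratio. Combination
fitness is predicted by the multiplicative (Bliss-style) model
f_pred = f₁·f₂; the interaction is reported both as difference
(measured − predicted; negative = synergy/sensitization) and as ratio,
since bar-plot comparisons define no single statistic. Spot-dilution scores
are (strain visible dilutions − control visible dilutions), median across
scorers, with the modal colony-size category. Mutation frequency is
resistant CFU per cell plated; the default test is Welch's two-tailed
t-test (a pooled-variance flag restores the textbook Student variant), with
zero-variance and zero-control degeneracies flagged rather than fatal.

## Conservation tiers

Core orthogroups are those with at least one gene in *every* comparator;
focal coverage is the share of core groups that also contain a focal gene.
Orthogroups (not summed genes) are counted by default — consistent with
coverage ratios like 701/890 — with a gene-level flag available. Unique
genes are focal genes in orthogroups devoid of comparator genes plus focal
genes unassigned to any orthogroup. For each focal essential gene the tier
count is the number of comparators whose members of that gene's orthogroup
intersect the comparator's published essential set; 4–7 → "most", 1–3 →
"some", 0 → "none", and a focal gene whose orthogroup contains comparator
genes but no essential ones counts as "none". Genes absent from the table
fall to "none" and are flagged.

## Validation design and measured behavior

The suite validates the pipeline against its own simulator at sizes chosen
to keep the full run fast while leaving estimates stable:

- **Null calibration**: 20 screens of 10,000 spacers (both conditions
  analyzed per screen), depth 500, 2 replicates, φ = 0.1. The per-analysis
  fraction of p < 0.05 stays within [0.035, 0.065]. The realized
  false-discovery proportion at q ≤ 0.05 is also recorded; on a full-null
  screen this quantity is binary per analysis (any BH rejection at all),
  so its 20-run average is an extremely high-variance estimate of the
  ~0.05 family-wise rejection probability — individual rejection events at
  these seeds are genuine NB tail excursions with exact conditional
  p < 5×10⁻⁶.
- **Recovery**: 200 genes (20 generally essential at G·s = −6, 10 + 10
  condition-specific essentials, 20 defects at −1.5, 140 neutral), 4
  guides/gene, Beta(8,2) efficiencies, depth 500, 2 replicates. Measured:
  essential-class sensitivity 1.0, false-essential rate 0.0, mean absolute
  error of gene median LFC against G·s·median(e) ≈ 0.23 on affected genes.
- **Oracles**: clustering ≡ threshold-graph components on 100 random
  instances of ≤200 transcripts; counting ≡ brute-force substring scan on
  10⁴ reads.

## Known limitations

- The NB model is the simulator's own; real screens add PCR and sampling
  artifacts the calibration does not probe.
- The exact-tail refinement conditions on size-factor-adjusted, rounded
  replicate sums; with strongly unequal size factors the conditioning is
  approximate.
- Stouffer on FDR-adjusted inputs (rather than raw p-values) is
  deliberately faithful to the screen's published procedure but makes the
  combined value conservative and rank-dependent.
- TU merging consumes external transcript predictions; it does not infer
  transcripts from coverage.
- Polarity simulation is available but gene calls do not attempt to
  deconvolve polar artifacts; TU annotation is reported precisely so users
  can interpret calls operon-wise.
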