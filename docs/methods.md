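# Methods

## Decay model and fitting

Transcription arrest makes each transcript's loss purely degradational, so
gene-level intensity follows I(t) = I(0)·e^(−kt) and ln I is linear in
time. All membranes (2 biological × 2 technical replicates per time point
by default) are pooled into one ordinary least-squares regression per gene
rather than fitting replicates separately and averaging: pooling uses the
full design in a single error model and gives a well-defined standard error
for the slope from all points combined. σ_k is defined as
100·SE(slope)/|slope|; an alternative reading — the SD of four per-replicate
slopes — exists, and the choice made here is recorded in every output's
provenance header (`sigma_k_definition`).

Classification: σ_k ≤ 30 % → *reliable*; σ_k ≥ 70 % **or** a non-negative
slope → *extremely stable* (a flat series within a ~20-minute window cannot
be quantified, and a positive slope would imply negative k); everything
else, and any gene with fewer than three usable time points, → *not
determined*. Both thresholds are configuration keys with these defaults.
Non-positive intensities are dropped point-wise, never imputed. The t = 0
reference point is part of the measured series and is included in the
regression. Half-life is t½ = ln2/k, defined only for reliable fits.

Normalization divides every membrane of a batch by the scalar mean
intensity of that batch's pre-arrest reference membrane. This cancels
whole-batch gains (labelling, exposure) exactly and leaves within-gene
slopes untouched; fits on normalized and raw data of a single batch are
identical.

## Units

Growth rates µ are supplied in h⁻¹ (the natural unit for doubling times of
hours) and converted to min⁻¹ (÷60) wherever they meet a degradation
constant, since half-lives are in minutes. Doubling time is ln2/µ, the same
formula as a half-life.

## Steady-state regulation analysis

V_T = (µ/60 + k)·[mRNA] balances synthesis against degradation and growth
dilution. `dilution_negligible` checks k ≥ 10·µ/60 (factor configurable):
a transcript must turn over an order of magnitude faster than the culture
doubles before the dilution term is dropped — true for the large majority
of bacterial mRNAs outside slow-growth extremes. Because no genome-wide
transcription-rate measurement exists, V_T is derived and reported for
diagnostics only.

ρ_D = −Δln k/Δln[mRNA] with ρ_T ≡ 1 − ρ_D enforced exactly. Genes with
|Δln[mRNA]| < ε (default 0.05) are reported *undetermined*: near-constant
concentrations make the ratio numerically unstable, and forcing them into a
bin would manufacture classifications. The five patterns I–V use a ±0.05
band around the exact points ρ_D = 1 and ρ_D = 0 for reporting; the
headline three-bin summary uses the strict edges ρ_D ≤ 0 / 0 < ρ_D < 1 /
ρ_D ≥ 1. The statistic is strictly pairwise; no multi-condition regression
is attempted.

Cross-condition comparability of concentrations: intensities are in
arbitrary units, so per-condition normalization leaves one free global
scale per condition. The analysis assumes equal total mRNA signal per
hybridization (standard practice: equal total-RNA input per labelling
reaction), under which reference-normalized t = 0 intensities are
comparable across conditions. The paired-data generator enforces the same
convention (below), making the assumption exact in simulation.

## Synthetic data

`generate_chase` emulates the chase design: per-gene k log-normal
(median half-life 5.8 min, ln-sd 0.5 by default — a fast-growth bacterial
distribution), a configurable fraction (default 0.2) of *extremely stable*
transcripts simulated with k exactly 0 to give an unambiguous truth class,
initial abundances log-normal (ln-sd 1.0) with V_T recovered from the
steady-state balance, default time grid 0, 1, 2, 4, 6, 10, 15, 20 min
(the real within-window sampling times are not standardized; the grid is
configurable), 2×2 replicate membranes per time point, per-batch log-normal
gains (ln-sd 0.1) and additive Gaussian noise on ln intensity (default
0.1), i.e. multiplicative log-normal intensity noise — chosen to match the
log-linear fitting model, as gene-level fluorescence errors are
scale-proportional. Identical parameters and seed give bit-identical data.

Not emulated: spot-level image artifacts, probe cross-hybridization,
membrane spatial effects, and any correlation between k and abundance.
Passing recovery tests therefore demonstrates estimator correctness under
multiplicative noise with batch gains, not robustness to structured
artifacts of real membranes.

`generate_paired_conditions` draws per-gene log fold-changes of [mRNA] with
magnitudes in [0.5, 1.5] (bounded away from the ε guard), balances their
signs so the multiplicative mean is ~1, and applies one common log-shift so
the total mRNA signal is conserved *exactly* across conditions — the
equal-total-signal convention above. Condition-b degradation constants are
then solved as k_b = k_a·e^(−ρ_D·Δln[mRNA]), so the designed ρ_D values
hold exactly and the full pipeline recovers them to machine precision on
noiseless data.

`simulate_feature_table` generates the determinant-model testbed: one
observation per gene per growth-rate level (486 × 3 by default), all
quantitative predictors standard normal, and

  ln t½ = 2.4 − 0.065·ln[mRNA] − 0.059·length + 0.030·|ΔG| + 0.029·CAI
          + growth effect (0.763 / 0.189 / −0.952) + N(0, 0.55),

with tAI, GC, position, functional category and motif class as null decoys.
The residual sd 0.55 is the analytic value at which the growth-dominated
signal yields pooled R² ≈ 0.63 while each within-condition model explains
almost nothing (≤ ~0.08) — the qualitative regime of interest: growth rate
as the major determinant, gene-specific features as small modifiers.

## Covariance model

Response ln t½; quantitative predictors z-scored so coefficients are
per-SD effects on log half-life and comparable across predictors (absolute
coefficient values are therefore transform-dependent; compare signs and
ranks across studies, not magnitudes — the model report says so in its
header). Qualitative predictors enter as treatment-coded factors; the motif
count is binned 0 / 1 / 2+ as a factor. Selection is bidirectional stepwise
from the full candidate model, accepting the single add/drop move with the
lowest AIC and breaking exact ties toward the smaller model; accepted moves
never increase AIC, so the final model's AIC is bounded by the full
model's. Rank-deficient candidate sets are repaired up front by removing
terms that add no design rank, reported in `dropped`.

Power note: stepwise AIC retains a term when its likelihood-ratio statistic
exceeds 2, i.e. roughly |t| > 1.41, so a term whose true |t| is ≈ 2 is
retained only ~70–80 % of the time. Recovery simulations that require
near-certain retention of every true term therefore use effect sizes giving
per-term |t| ≈ 4 at the 486×3 design (−0.10, −0.09, +0.06, +0.06 with
residual sd 0.60, R² ≈ 0.6) — the detectability threshold is a property of
AIC at this sample size, not of the estimator. At the smaller default
effects the strong terms (concentration, length, growth rate) are still
selected essentially always and estimated without bias.

`growth_rate_only_r2` refits the same selected-model machinery within each
growth-rate level with the growth factor withheld; the collapse of R²
relative to the pooled model quantifies how much the growth rate alone
explains.

## Sequence features

CAI: codon counts pooled over a user-supplied reference set (typically
ribosomal-protein CDS); relative adaptiveness w = count/max within each
synonymous family, pseudo-count 0.5 for codons never observed; CAI is the
geometric mean of w over the gene's codons, excluding stop codons and the
single-codon families Met and Trp whose w = 1 carries no information. tAI:
per-codon absolute weight Σ(1−s)·copies over the Watson–Crick anticodon
and the standard wobble pairing (penalties s: G:U 0.41, I:C 0.28, I:A
0.9999, U:G 0.68; overridable), normalized to the maximum; geometric mean
over codons, with unserved codons (weight 0) excluded with a warning
rather than zeroing the index. Upstream windows are the 101 nt from −100
to +1 relative to the first base of the start codon (1-based, strand-aware,
truncated with a warning at sequence bounds); motif counting is
overlapping, given-strand only. Folding free energies are accepted as a
two-column table from a standard folding tool run at the culture
temperature; |ΔG| is the model feature. No internal structure prediction
and no de novo motif discovery.

## Clustering

Ward minimum-variance linkage on Euclidean distances between half-life
profiles, raw minutes by default (all coordinates share units; a log option
exists since the choice is not settled). Flat cut by requested cluster
count — the count is chosen by inspecting the dendrogram, not automated.
Cluster summaries report per-condition means with two-sided t-intervals
(default 95 %); singleton clusters get an undefined interval.

## Problem sizes and numerical choices

Recovery checks use 2000-gene chases (8 time points × 4 membranes), 500-gene
paired conditions, 486×3 determinant tables with 10–50 selection replicates,
and 486-profile clustering — sizes at which the Monte-Carlo error of each
checked statistic is several-fold smaller than its acceptance margin.
Stepwise AIC comparisons use a 1e-9 tie tolerance; fits refuse series with
fewer than three distinct time points; ρ_D is never computed across a
concentration change smaller than ε. All generators take explicit integer
seeds and are bit-reproducible.

## Known limitations

- σ_k as SE-of-pooled-slope is one of two defensible readings (see above).
- The equal-total-signal assumption is untestable from intensities alone;
  violations shift every Δln[mRNA] by a constant and bias ρ_D multiplicatively.
- Covariance-model coefficients are only sign/rank-comparable across
  transforms; the package deliberately reports z-scored effects.
- The extremely-stable class is simulated at k = 0 exactly; real "very
  stable" transcripts have small positive k, so the simulated class is
  cleaner than reality.
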