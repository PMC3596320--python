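# mrnastab

Genome-wide mRNA stability analysis from transcription-arrest (rifampicin
chase) time courses, for microbial transcriptomics: per-gene degradation
rate constants and half-lives, partition of mRNA-level changes between
transcriptional and degradational control, covariance modelling of
half-life determinants, and clustering of half-life profiles across growth
conditions. A synthetic-data generator with exact ground truth backs every
stage, so estimator accuracy can be measured rather than assumed.

## The model

After rifampicin blocks transcription initiation at t = 0, each transcript
decays first-order, so on gene-level intensities I_g(t):

    ln I_g(t) = ln I_g(0) − k_g · t

`mrnastab` fits this by ordinary least squares over all replicate membranes
pooled (after normalizing each batch to its pre-arrest reference membrane),
reports t½ = ln2 / k_g, and classifies each fit by σ_k, the standard error
of the slope in percent of its magnitude: *reliable* (σ_k ≤ 30 %),
*extremely stable* (flat/rising series or σ_k ≥ 70 %; the chase window is
too short to quantify these), or *not determined*.

At steady state, transcription balances degradation and growth dilution,

    V_T = (µ + k) · [mRNA]        (µ converted h⁻¹ → min⁻¹),

and for transcripts turning over much faster than the culture doubles the
dilution term drops. A concentration change between two steady states then
decomposes into regulation coefficients

    ρ_D = − Δln k / Δln[mRNA],    ρ_T = 1 − ρ_D,

the opposite slope of the ln k vs ln[mRNA] plot across conditions. ρ_D = 1
is pure degradational control, ρ_D = 0 pure transcriptional, 0 < ρ_D < 1
shared, ρ_D > 1 and ρ_D < 0 antagonistic regimes dominated by degradation
and transcription respectively.

Half-life determinants are modelled by ANCOVA: ln t½ regressed on z-scored
quantitative predictors (mRNA concentration, gene length and position, CAI,
tAI, GC content, |ΔG| of the −100..+1 upstream region read from folding-tool
output) and factor predictors (functional category, growth-rate level,
upstream AGGAG motif-count class), with bidirectional stepwise selection
under AIC. Half-life profiles across growth rates are clustered with Ward's
minimum-variance linkage.

## Worked example

Simulate two paired steady states (µ = 0.51 vs 0.11 h⁻¹, 500 genes,
10 % multiplicative intensity noise) in which 90 % of genes were constructed
with ρ_D ≤ 0, then run the full pipeline:

```python
import numpy as np
from mrnastab import (SynthParams, generate_paired_conditions,
                      normalize_to_reference, fit_all, mrna_concentrations,
                      compare_tables, summarize_regulation, summarize_halflives)

n = 500
rng = np.random.default_rng(0)
targets = np.where(rng.random(n) < 0.9,
                   rng.uniform(-2.0, -0.2, n), rng.uniform(0.2, 2.0, n))
fast = SynthParams(n_genes=n, mu=0.51, halflife_median=5.8,
                   frac_extremely_stable=0.0, seed=1)
slow = SynthParams(n_genes=n, mu=0.11, halflife_median=11.4,
                   frac_extremely_stable=0.0, seed=2)
paired = generate_paired_conditions(fast, slow, targets)

def fit(ds):
    norm = normalize_to_reference(ds.intensities)
    t = fit_all(norm)
    t["mrna"] = mrna_concentrations(norm)
    return t

s = summarize_halflives(fit(paired.a))
print(f"fast growth: {s['n']} reliable fits, median t1/2 = {s['median']:.1f} min,"
      f" mean = {s['mean']:.1f} +/- {s['sem']:.1f} min")
res = compare_tables(fit(paired.a), fit(paired.b))
print(summarize_regulation(res).round(1))
```

prints

```
fast growth: 500 reliable fits, median t1/2 = 5.5 min, mean = 6.5 +/- 0.2 min
                        n_genes   pct
bin
mainly_transcriptional      425  88.4
shared                       29   6.0
mainly_degradational         27   5.6
undetermined                  0   NaN
```

The recovered median half-life matches the generator's 5.8-min calibration
to within sampling error, and the regulation summary recovers the designed
90/10 split of mainly-transcriptional vs other control to within two
percentage points despite the noise (at zero noise the recovery is exact).

The same stages are available from the shell — `mrnastab simulate | fit |
regulate | features | model | cluster | report`, all operating on
provenance-stamped TSV files; `mrnastab report --config pipeline.yaml` runs
a whole configured pipeline.

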