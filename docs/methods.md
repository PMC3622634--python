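# Methods

## Overview

`admixhmm` infers population stratification and SNP-resolution local
ancestry from a sample of N unrelated diploid individuals, with no
reference panel required. It separates the problem into two Markov layers
fitted in sequence: a *haplotype segmentation* layer that converts reads,
genotypes or phased haplotypes into segments of shared ancestral haplotype
states, and an *admixture* layer that clusters those segments into
populations along the genome. Both layers use the same infinite-state
machinery: a stick-breaking prior over an unbounded label set, a collapsed
"super" state holding all unoccupied labels, and forward-summation /
backward-sampling updates.

## Haplotype segmentation layer

Inputs are per-SNP per-individual read counts for the two alleles
(modelled as independent Poissons with means `coverage × g/2` and
`coverage × (2−g)/2` for minor-allele dosage `g`, means floored at 1e-6),
or haplotypes directly, in which case the read layer is skipped. Each of
the 2N haplotype chains follows a Markov chain over haplotype states;
state `s` at SNP `j` emits the minor allele with a state-specific
Bernoulli frequency, estimated with add-one smoothing,
`θ_sj = (y+1)/(n+2)`. Chains switch state between SNPs j−1 and j with a
per-SNP probability carrying a Beta(α·r0, 1−α·r0) prior (α = 0.2,
r0 = 0.05); the stick-breaking prior over states regularizes the number of
states discovered.

Fitting is a blocked Gibbs sampler (default 10 burn-in + 10 sampling
sweeps): each sweep refreshes the emission tables, samples switch rates
from their Beta posteriors and stick weights from their posterior, then
redraws all chains by forward-filtering/backward-sampling, vectorized
across chains. When the input is read counts, the two chains of an
individual are updated jointly over state pairs so the genotype likelihood
factors correctly, and haplotypes are resampled given states and reads.
Numerical choices: the first 3 sweeps hold the switch rate at r0 (before
any transitions have been observed the posterior rate is near zero and
chains could never move); a few random state splits during burn-in seed
new states; super-state visits are converted to fresh labels drawn from
the residual stick. Output: posterior-mode states S, transition indicators
Φ, per-SNP recombination probabilities r_j (posterior mean transition
frequency across chains, floored at 1e-6 so downstream Beta/Dirichlet
priors stay proper; r_j at the first SNP is fixed at 0), and called
haplotypes H. We define r_j as the mean per-chain transition frequency;
other normalizations across the 2N chains would differ by a constant
factor absorbed by α.

Segments are maximal runs of constant state; double-recombination sites —
SNPs where both of an individual's chains transition — are the candidate
phasing switch-error locations.

## Admixture layer

Population-origin chains Q (one per haplotype) with event indicators I
emit the haplotype segments. Within a segment `[a, b]`, SNP emissions
`Pr(s_j | q)` are raised to the weight
`w = (1 + Σ_{j'=a+1..b} r_{j'}) / (b−a+1)`, making the segment contribute
the geometric mean of its per-SNP probabilities to the power of the
expected number of recombination events — one-plus-expected-recombinations
effective observations, since SNPs within a segment are redundant. An
alternative scheme (`weight_scheme="first_snp"`: weight 1 at the segment's
first SNP, r_j elsewhere) is available. Phasing switch errors are handled
by summing over a switch state δ per double-recombination block with
switch probability ε = 0.5: under δ = 1 a population on one strand emits
the other strand's states with that strand's weights. The δ chain is
anchored at 0 before the first block; at ε = 0.5 the anchor is immaterial
(asserted in tests).

The prior over (Q, I): chain starts and event redraws draw from stick
weights v_q (V_q ~ Beta(1,1)); the per-SNP admixture rate γ_j has a
Dirichlet(α r_j, 1−α r_j) prior and is integrated out, leaving per SNP the
Beta-binomial factor Γ(ξ_j+αr_j)Γ(2N−ξ_j+1−αr_j)/(Γ(2N+1)Γ(αr_j)Γ(1−αr_j))
over the total event count ξ_j. Events are restricted to haplotype segment
boundaries; a redraw may land on the current population, so I = 1 does not
force a visible label change (the transition-matrix convention
diag(1−γ) + γ·1v′).

### Fitting

Per iteration (default 20 burn-in + 30 sampling sweeps): update the
emission table `Pr(s|q) = (y+1)/(n+K_j)` (per-SNP co-occurrence counts
over all 2N chains; an unoccupied population gets the uniform row 1/K_j,
its prior predictive); then update each individual in index order by
forward-summation/backward-sampling over the joint state `(q1, q2, δ)`
with q ranging over occupied labels plus the super state; then sample
stick weights from V_q ~ Beta(c_q+1, Σ_{t>q}c_t+2), where c_q counts
occurrences of q at events or chain starts. Because nothing can change
between an individual's event positions (segment starts of either chain,
double-recombination sites), the recursion runs at event resolution with
interval emission log-sums precomputed — exact, and linear in the number
of events rather than SNPs.

The per-individual conditional uses the exact sequential Beta-Bernoulli
pair predictive with γ_j collapsed: P(I1=1) = (ξ_j^(−i)+αr_j)/(2N−1) and
P(I2=1 | I1) = (ξ_j^(−i)+I1+αr_j)/2N, where ξ^(−i) counts the other
chains' events at j and a chain without a boundary at j contributes a
forced zero. Backward passes either sample (default — helps escape local
modes) or maximize (exact joint Viterbi over Q, I and δ, lowest label
index on ties). Super-state selections become concrete labels drawn from
the residual stick (sequential Beta(1,1) sticks inside the super mass, so
the first unused index is the likeliest); the label set is compacted every
sweep.

Initialization puts everyone in one population with no events and applies
one forced random split. During burn-in, `n_random_splits` (default 3)
additional splits relabel a random subset of one population's
constant-label runs to a fresh label — run boundaries already carry
events, so the move preserves the (Q, I) invariants.

**Burn-in annealing.** At realistic sizes the per-chain conditionals carry
tens of nats, so a plain Gibbs sweep freezes in the first configuration it
reaches and neither splits nor the super state can reorganize it. The
emission evidence is therefore tempered during burn-in: log-emissions are
scaled by τ, rising geometrically from 0.1 to 1 across the burn-in sweeps.
Splits are scheduled in the soft early phase. Sampling sweeps run at τ = 1,
so the collected posterior is untempered. Merging of spurious
sub-populations is only possible while τ < 1: with point-estimate emission
tables there is no Occam penalty, and a superfluous population fits its
own members at least as well as the merged one, so it persists once the
evidence hardens (see Limitations).

**Reference mode.** With C known populations (labeled references, or a
fixed K alone), the stick prior is replaced by a symmetric Dirichlet(1,…,1)
over C labels, the super state is dropped, and reference chains stay
pinned to their labels at every SNP while contributing to the emission
tables, event counts and label weights. Referenced fits skip the annealing
ramp — the references anchor the labels from the first sweep, and
tempering would let the free majority lock into a label-swapped mode that
a handful of reference chains cannot overturn. For the same reason the
first sweep's emission table is built from the reference chains alone;
sample chains join from the second sweep.

Posterior summaries are per-SNP: MAP label and label frequencies per
haplotype, the MAP number of distinct populations, and the mean
admixture-event rate. De novo labels are relabeled densely by first
appearance along the genome; reference-mode labels keep the reference
numbering.

## Synthetic data

The generator emulates the benchmark conditions end to end. Ancestral
panels follow a Balding–Nichols divergence model: ancestral frequency
p ~ Uniform(0.05, 0.95) per SNP, population frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F) with fixation index F (default 0.2 —
long-diverged, well-separated populations), and a pool of 20 template
haplotypes drawn per population, which gives the sample realistic
linkage disequilibrium through mosaic copying. Each simulated individual
draws a founding population from the admixture proportions (both
haplotypes start there, so λ = 0 yields cleanly stratified individuals);
along the genome each haplotype admixes independently with per-SNP event
probability 1 − exp(−λ d_j) under the genetic map (events redraw the
population from the proportions and may land on the same one), and
switches template within its population at 1 per 200 kb in expectation.
Reads are Poisson at the configured coverage (8× default) with no
sequencing error by default (an optional per-read flip probability exists
but the Poisson model has no base-error term). Non-polymorphic SNPs can be
removed with `filter_nonpolymorphic`, mirroring the post-calling cleanup.

What the generator does *not* emulate: coalescent genealogies (templates
are exchangeable iid draws, so there is no within-population allele-age
structure), mutation, genotyping batch effects, or multi-chromosome
bookkeeping. Passing benchmarks on these panels therefore demonstrates the
machinery under idealized LD, not performance on real cohorts.

Benchmark scales are desk-sized reductions of two full-scale designs. For
stratification we keep an ~8 Mb region and subsample to 2,000 SNPs (4 kb
spacing): this preserves ~40 within-population copying segments per chain,
the quantity that drives individual clustering; a short dense region gives
chains so few segments that finite template co-usage masquerades as
sub-structure. For local ancestry we keep dense-sequencing spacing
(750 bp, ~1 cM/Mb) and shorten the region to ~3.75 Mb at 5,000 SNPs: this
preserves ancestry-block length in SNP units, the quantity that governs
per-block evidence and boundary placement.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α | 0.2 | strength of the Dir(αr_j, 1−αr_j) admixture-rate prior |
| ε | 0.5 | phasing switch-error probability at double-recomb sites |
| weight scheme | segment_mean | per-SNP emission weights within segments |
| n_burnin / n_samples | 20 / 30 | admixture-layer sweeps |
| n_random_splits | 3 | burn-in splits (de novo fits) |
| anneal_start | 0.1 | initial emission temperature τ during burn-in |
| max_pops | 30 | truncation of the label set |
| hapseg base_rate r0 | 0.05 | prior per-SNP haplotype switch level |
| coverage | 8× | mean Poisson sequencing depth |
| within-pop recombination | 1/200 kb | template switch rate in the simulator |
| fixation F | 0.2 | Balding–Nichols divergence of synthetic panels |

## Numerical and degenerate-input choices

Log-space throughout; forward messages renormalized per event with the
log-normalizer accumulated (the emission proportionality constant cancels
in sampling). Ties in MAP and label assignment go to the lowest index.
All randomness flows from a single seeded generator in fixed order;
identical seeds give bitwise-identical outputs. L = 1 inputs reduce to
emission-only clustering. A segmentation without internal boundaries makes
admixture undetectable by construction (events are restricted to
boundaries) — this is a property of the model, not an error. With flat
data and one individual, the Beta(1,1) stick puts probability exactly 1/2
on the two chains sharing a population, so the sampled per-SNP population
count is not degenerate at 1; the joint-MAP configuration is.

## Limitations

* De novo fits at very old admixture (λ ≈ 216 at desk scale) over-split:
  point-estimate emission tables provide no marginal-likelihood penalty
  for duplicate populations, and once the annealing ramp ends superfluous
  labels cannot merge. Supplying the population count (0-ref mode)
  restores accuracy; the information ordering (2 refs ≤ 0 refs ≤ de novo)
  holds throughout.
* Local-ancestry boundary placement is limited by the segmentation layer:
  ancestry switches can only be placed at inferred segment boundaries, so
  errors scale with boundary blur relative to ancestry-block length.
* The haplotype layer is a simplified sampler over the published sketch of
  the segmentation model; numerical equivalence with the original
  program is not claimed.
* Single chain, single machine; for hard instances run several seeds and
  compare (the fit is deterministic given a seed).
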