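# Methods

## Model

A nest is N insects, each described by one coarse-grained molecular
state: the concentration of queen-gene products, scaled so that the
unrepressed production/degradation balance sits at r = 1. Time is
measured in units of the degradation time of those products (~30 h for
the biology that motivated the defaults), so the scaled degradation rate
is 1. The state lumps hormonal, pheromonal, and transcriptional
regulation into a single degree of freedom; the only structural
assumptions are (i) a stable high-expression attractor under isolation
and (ii) repression of the loser's expression by dominance contests.

Contests between i and j occur with rate weight
K(rᵢ, rⱼ) = rᵢ rⱼ σ(rᵢ − rⱼ) for "i subdominant to j". The
discrimination function σ must only decrease monotonically on a scale
1/λ; we fix the logistic σ(x) = 1/(1 + exp(λx)) because it yields the
exact complement identity σ(x) + σ(−x) = 1 (the two directions of a pair
sum to rᵢ rⱼ) and a closed-form inversion between the dominance error
rate and λ used in estimation. Nothing downstream depends on the tail
shape beyond this scale.

Two stochastic levels are simulated exactly (Gillespie):

* **Reduced model** — molecule counts nᵢ (r = n/n_ss): production at
  rate n_ss, degradation at rate nᵢ, and subdominant interactions at
  rate α·K which remove m molecules (floored at zero: counts cannot go
  negative). n_ss sets the Monte-Carlo granularity; default 50, a
  documented sensitivity knob (demographic noise scales as √(r/n_ss)).
* **Full model** — counts plus a repression flag qᵢ: production
  μ(1 − qᵢ), degradation δnᵢ, repression decay q: 1→0 at rate Γ, and
  contests flipping the loser's q: 0→1 at rate ω·K. Repression decay is
  Markovian (constant Γ); the printed time-since-interaction dependence
  of the decay is supplementary-only, and the constant-Γ choice is the
  memoryless default. For fast repression cycles the full model reduces
  to the reduced one with m ≈ μ/Γ (verified by a two-model comparison
  test).

Interaction channels are sampled through the complement identity: an
unordered pair is drawn with probability ∝ rᵢrⱼ (total rate
α(S² − Q)/2 with S = Σr, Q = Σr²), then the subdominant member with
probability σ(rᵢ − rⱼ). This is an exact decomposition of the ordered
rates, not an approximation; in the full model the flip applies only to
unrepressed losers (exact thinning) while every encounter is logged as a
fight. Cores are numba-compiled with explicit integer seeds; identical
(parameters, seed) give identical trajectories.

### Parameters (scaled units)

| symbol | meaning | default | why |
|---|---|---|---|
| N | insects per nest | 16 | typical nest census in the motivating study |
| α | per-individual interaction rate | 4.625 | 3.7 fights/day × 30 h degradation time |
| λ | discrimination steepness | 24 | lower bound from 0/17 queen losses (see estimation) |
| m | molecules removed per loss | 5 | m/n_ss = 0.1 concentration units; with N=16 gives α̃_eff ≈ 6.9, inside the single-queen region |
| n_ss | steady molecule count | 50 | granularity knob |
| Γ | repression release rate | 1 | repression persists about one degradation time (30 h molecular stability) |
| ω | contest rate constant (full) | 10 | reproduces per-capita fight rates of a few per degradation time |

`nondimensionalize` converts physical rates: α = (fights/day) ×
(degradation time in days).

## Mean-field limit

The printed transport form of the mean-field equation lacks an explicit
density factor in the advection term and is dimensionally inconsistent
as written; we implement the standard conservative form

∂τ f + ∂r[v f] = 0, v(r) = (1 − r) − α̃ r ∫ r′ σ(r − r′) f̂(r′) dr′,

with f̂ the unit-mass (per-capita) density. This reproduces the
published attractors exactly. Matching a finite nest to the mean field
gives α̃_eff = α·m·(N − 1)/n_ss (each insect is suppressed by N − 1
others); where α̃ is used directly it is a free parameter. The kernel's
argument order follows the behavioral definition (lower expression
loses); the opposite order that appears once in the mean-field printing
is treated as a typo.

**Numerics.** First-order upwind finite volume on [0, 1.5], 400 cells
(default), explicit stepping at CFL 0.5. The interaction integral is
refreshed every 8 CFL steps (it evolves on the advective time scale, ~300
steps). Boundary fluxes are zero and the drift points inward at both
ends, so mass is conserved to round-off and positivity is preserved by
the upwind property. Delta-like initial conditions are represented as
Gaussians two cells wide. The steady peak aliases within one cell, so
closed-form comparisons use a two-cell-width tolerance.

**Coherent-population reduction.** A colony that remains a single peak
at r̄ obeys dr̄/dτ = 1 − r̄ − α̃r̄²/2 (members suppress each other with
the tie weight σ(0) = 1/2), giving the steady mean
r̄\* = (√(2α̃+1) − 1)/α̃. The formula is printed in the source text with
the radical lost in typesetting ("(2α̃+1−1)/α̃"); the √ reading is
adopted because it is this fixed point and has the correct α̃ → 0 limit
of 1, and it is verified numerically against the PDE rather than
assumed. A tracer individual in the frozen colony drifts with
dr/dτ = 1 − r − α̃ r r̄ σ(r − r̄): bistable between
r₂ = 1/(1 + α̃r̄) (worker) and r₀ = 1 (queen), with the unstable plastic
state at r̄ itself. Sweeping r̄ as a frozen control parameter traces the
saddle-node bifurcation; the fold is located by bisection on the root
count.

**Stability caveat.** Linearizing the tracer dynamics at the coherent
peak gives growth rate −1 − α̃r̄/2 + α̃λr̄²/4: for
λ > 4(1 + α̃r̄/2)/(α̃r̄²) (≈ 10 at α̃ = 1) the coherent peak is unstable
to rank-ordered spreading — insects above the peak escape suppression
and the PDE develops a spread worker band below a queen mode. The
attractor identities are therefore checked on the reduction at λ = 24
(tolerance 0.03, covering the finite-λ discrimination tail
~(1 − σ(r₂ − r̄))(1 − r₂) ≈ 0.02 plus grid error), while PDE/closed-form
and PDE/stochastic comparisons use λ = 0, where the colony provably
stays coherent and the demographic width √(r/n_ss) ≈ 0.12 (at n_ss = 50)
sets the preregistered Wasserstein-1 tolerance of 0.15.

**Perturbations.** Intrinsic = displace one tracer with the colony
frozen; magnitudes below the separatrix gap relax back (suppressed).
Extrinsic = a coherent diagonal displacement of population structure and
tracer together (queen removal drops the structure to the workers'
level); the colony then climbs back to r̄\* carrying the tracer to the
plastic state, from which a new queen can emerge (reprogrammed). The
zero-magnitude perturbation is classified suppressed by construction.

## Queen removal and the activity prediction

`queen_removal_experiment` settles a nest, removes the individual with
the highest trailing-average expression, and simulates the remaining
N − 1. In the full model the default clears the workers' repression
states at the removal: the queen's dominance (and the signaling
associated with it) is what maintains her nest mates' repression, so the
nest relaxes from a queenless, unrepressed, low-expression configuration
— the same initial condition used for the reprogramming simulations.
The collective upregulation that follows drives a surge of fighting
(rates ∝ rᵢrⱼ) before dominance re-establishes order. With repression
states carried through the removal instead (available as an option),
worker-worker policing maintains the repressed state and no surge
occurs; only the structural reorganization (a new single queen) remains.
The activity proxy is windowed interaction events per insect per unit
time; the queenless (eggless-phase) analogue is the first few
degradation times after removal. Egg-layer counts use window-averaged
expression against the attractor-midpoint threshold
(1 + 1/(1 + α̃_eff r̄\*))/2 — a parameter-free separatrix proxy — with an
absolute fallback of 0.5 (half the unrepressed steady state) when the
coupling vanishes and the midpoint degenerates to 1.

## Queen persistence

The closed form T = T_int(R + 1/[1 − (1 − e^{−R})^N]) is the expectation
of a window model: in each interaction window of length T_int every
worker independently escapes its reset with probability e^{−R}; the
number of windows to the first escape is geometric and the escaping
worker needs a further R·T_int of unperturbed drift. The Monte-Carlo
oracle simulates exactly this process by default. A continuous renewal
variant (exponential or deterministic gaps, challenge when a gap exceeds
R·T_int) is provided for sensitivity: the exponential-gap version is
substantially shorter than the window model (e.g. 1.74 vs 3.72 T_int at
N = 1, R = 1 — inspection bias of long gaps), and the deterministic-gap
version never challenges for R ≥ 1. T is increasing in R and
*decreasing* in N: more workers means the first chance activation
arrives sooner. At R = 0 every window activates and T = T_int; the +inf
flag appears only in the diverging large-R (or σ → 0) limit.

The noise variant replaces the per-window activation probability with
the upper-tail mass of the worker expression distribution beyond the
unit activation threshold: e^{−1/σ} for exponential tails; for the
normal tail — no printed formula exists — the Gaussian upper tail
Φ̄(1/σ) at scale σ, matching the same template. σ is used as the scale
parameter exactly as printed (e^{−1/σ}); an interpretation as a variance
would only relabel the axis.

## Parameter estimation

* Interaction rate: total fighting (subdominant) events divided by the
  night-time census N and the observation time in days; SEM across
  individuals. 74 events / 20 insects / day = 3.7 per day.
* Dominance error rate: k losses in n queen fights → k/n, with one
  pseudo-observed loss at k = 0, so 0/17 → 1/17. (The source describes
  this as a beta-prior maximum-likelihood estimate; the pseudo-count
  rule is the convention that reproduces the printed value exactly.)
* Asymmetry bound: inverting the logistic across the steady queen-worker
  expression gap Δ gives λ = ln((1 − ε)/ε)/Δ; ε = 1/17 with Δ ≈ 0.116
  gives λ ≈ 24. Δ defaults to the mean-field gap 1 − r₂(α̃) and is
  overridable, since the published mapping between ε and λ lives in
  inaccessible supplementary material; λ ≈ 24 is treated as a soft
  anchor, not a machine-checked constant.

## Observables

Behavior indices follow the six-type ethogram (DOM, SUB, DEC, REC, TR,
ANT), with each dyadic fight stored as a DOM row for the winner and a
SUB row for the loser so the indices are direct row counts: interaction
rate = all events per hour observed; fight index = (DOM+SUB)/all;
dominance index = DOM/(DOM+SUB), missing without fights. Phase
comparisons use the Wilcoxon signed-rank test when a pairing id links
observations and the Mann-Whitney rank-sum otherwise (insects collected
at a phase cannot be resampled later, so unpaired is the default), with
Benjamini-Hochberg correction at 0.05. Ovary maturity is called at
≥ 1.5 mm (inclusive), the smallest egg size associated with laying.
Global activity is the mean absolute per-pixel difference between
consecutive frames, normalized by the number of wasps and the squared
spatial scale; the calibration constant is camera-specific, so only
relative comparisons are meaningful.

The gene-variability analysis is a deliberately simplified
over-dispersion test, not the published technical-noise decomposition:
per-gene variance across workers is compared to a quadratic
log-variance/mean trend fitted across all genes, scored by the χ²
upper tail of (n−1)s²/trend, BH-corrected at 0.05; the fraction of
significant genes is reported per methylation bin and a Pearson test is
run on the unbinned (methylation, log over-dispersion) pairs. The test
asks the same qualitative question (which genes vary more than genes of
similar expression) without external tooling; its absolute fractions are
not comparable to the published pipeline's.

## Synthetic data

Generators mirror the study design — control → eggless → D1/D4/D14, N =
16, ~45 min observation per phase, 10⁴ genes of which 200 are
queen-associated — without claiming to reproduce its data. Fights are
Poisson at 3.7 subdominant events per insect per day (×3, queenless, in
the eggless phase); the queen wins at 1 − ε with ε = σ(Δ, λ) ≈ 1/17.
Expression is log-scale Gaussian with per-gene noise sd
0.6·exp(−1.5·methylation), methylation ~ Beta(2,2); queen genes carry a
heterogeneous per-gene fold-change pattern (Gamma-distributed), shared
between control queens and the D4 cohort, because a uniform shift would
be invisible to profile correlations. Ovary size grows with the realized
queen-gene score in control (queens exceed 1.5 mm by construction); at
D4 only the new queen is mature. Everything derives from one seed fanned
out into independent substreams, and every ground-truth parameter is
exposed so downstream analyses are tested as estimator-recovery
problems.

What the generator does **not** emulate: transcriptome covariance
structure (genes are independent given the queen pattern), sequencing
counts (values are Gaussian on log scale, not negative binomial reads),
identity tracking between behavioral and expression cohorts, and
anything at the sequence level. Passing recovery tests therefore shows
the estimators are correct under the assumed statistical structure, not
that they are robust to real-data artifacts (batch effects, count noise,
unbalanced observation).

## Problem sizes and test design

The test suite and the acceptance script run on one CPU in minutes;
sizes were chosen as the smallest that make the statistical claims
crisp: stochastic/mean-field comparison at N = 200 over 60 time units;
phase-diagram cells at N = 8 with 20 replicates over 120 time units (the
single-queen demonstration cell is α = 20, λ = 80, deep in the
frequent/asymmetric regime; the empirical point α ≈ 4.6, λ ≈ 24 is also
single-queen but with the short queen tenures the persistence analysis
predicts, so modal classification there is noisier); queen-removal
statistics over 20–30 seeds; persistence oracle at 10⁴ replicates;
estimator recovery on 10–20-day synthetic logs; the type-I-error check
over 100 seeds with a one-sided (negative and significant) detection
rule, whose null rate is ~2.5%.

## Known limitations

* The mean-field PDE at strong discrimination develops the rank-ordered
  band structure discussed above; the closed-form attractor identities
  hold for the coherent reduction, and only approximately (≈ 0.02–0.15
  depending on λ and α̃) for the band edges of the full PDE.
* The repression-release interpretation of queen removal is a modeling
  decision; with persistent repression states the model predicts no
  activity surge.
* The reduced model floors molecule counts at zero, which slightly
  biases the suppression strength at very low expression.
* Dominance direction within a sampled pair uses σ on the instantaneous
  states; refractory or memory effects (the time-dependent repression
  decay of the printed master equation) are not modeled beyond the
  constant-Γ approximation.
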