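# Methods

## Model

A windowed genomic track `y_1..y_L` is modelled with a hidden Markov
chain `θ_1..θ_L` over `K` states. Two emission families are supported:

- **Normal**: `y_l | θ_l = i ~ N(μ_i, σ²)`, one shared σ, means strictly
  increasing.
- **Gamma-Poisson**: latent intensity `λ_l | θ_l = i ~ Gamma(α, β_i)`
  (shape–rate parameterisation; state mean `α/β_i`), count
  `y_l ~ Poisson(λ_l)`. One shared shape α, rates strictly decreasing so
  state means increase. Marginally `y_l | θ_l = i` is negative binomial
  with size α and success probability `β_i/(1+β_i)`.

Sharing the dispersion parameter makes the log-density difference between
two states monotone in `y` (checked by `check_convex_ordering` and
property-tested), so the states admit a total order by emitted mean.
Transitions are restricted to order-neighbours: **T** is tridiagonal,
with off-band entries structurally zero (validated exactly, not by
tolerance). The initial distribution is the stationary distribution π of
**T**, obtained by solving the linear system `πT = π`, `Σπ = 1` directly
(deterministic; no power iteration). A tridiagonal stochastic chain is a
birth–death chain and hence reversible with respect to its own π; the
`detailed_balance_residual` helper is the numerical audit of that fact.
Matrices with a zero sub/super-diagonal are reducible; validation flags
them and `stationary_distribution` refuses them, because the stationary
prior is only well defined for an irreducible chain.

Free parameters: `K` location parameters + 1 shared dispersion, `2K − 2`
transition entries, and no separate initial distribution (reversibility
ties it to **T**): `3K − 1` in total, versus `K(K+2) − 1` for an
unordered HMM with per-state dispersions.

## Sampler

One sweep of the Gibbs sampler:

1. **Path draw.** Emission log-densities under the current parameters
   (for counts: the Gamma(α, β_i) density of the current latent λ_l —
   given λ the counts carry no extra information about θ) feed a scaled
   forward pass; a full path is drawn by backward sampling. This is a
   joint draw of the path from its exact conditional, and under a
   tridiagonal **T** every sampled path is adjacent-only by construction.
2. **Emission updates**, all from unconstrained conditionals:
   - Normal: `μ_i | σ, path ~ N` conjugate update on the observations
     assigned to state i; then `σ² | μ, path ~ InvGamma(a0 + L/2,
     b0 + SSR/2)` pooling residuals across states. Empty states draw
     from the prior.
   - Gamma-Poisson: `λ_l ~ Gamma(α + y_l, β_{θ_l} + 1)` per position;
     `β_i ~ Gamma(a0 + n_i α, b0 + Σ_{l∈i} λ_l)`; then a
     Metropolis–Hastings step on log α with a Gaussian proposal
     (sd 0.1 by default; the α'/α Jacobian is included in the ratio).
3. **Ordering enforcement.** The joint relabelling sort permutes
   emission parameters, the path, and the path's transition-count matrix
   into ascending-mean order (stable sort; exact ties are flagged but
   occur with probability zero). Sorting *before* the row draw keeps the
   Dirichlet support aligned with the labels.
4. **Transition rows.** Each row i is drawn from a Dirichlet over its
   band support with parameters (sorted transition counts +
   concentration c, default 1); off-band zeros are structural. π is then
   recomputed from the new **T**. The initial-state likelihood term is
   *not* included in the row conditionals — rows are treated as
   independent Dirichlets, the standard long-sequence approximation (the
   coupling term is O(1) against O(L) transition counts).

**Recording convention.** The trace stores, per retained iteration, the
parameters that produced that iteration's forward pass together with its
marginal log-likelihood, so every trace row is internally consistent and
the recorded log-likelihood can be reproduced exactly by re-running the
forward pass at that row's parameters (asserted to 1e-9 in the tests).
For counts, the recorded value is the *negative-binomial marginal*
forward likelihood (λ integrated out), computed on retained iterations;
this is the quantity that is comparable across K and across families and
is the one used in the model-selection table. The per-window state
probabilities reported in a fit are the across-iteration average of the
per-sweep smoothing distributions (a Rao-Blackwellised estimate of
`Pr(θ_l | y)`), the hard assignment is its argmax, occupancy the hard
state fractions, and the position posterior mean is
`Σ_i γ̄_l,i · mean_i` with posterior-mean state means.

**Priors.** Defaults are diffuse conjugate priors centred on
method-of-moments estimates of the data: normal means `N(ȳ, (3·sd(y))²)`,
variance `InvGamma(2, var(y))` (prior mean var(y)), rates
`Gamma(1, b)` with prior mean `α_mom/ȳ`, shape `Gamma(1, 1/α_mom)` with
`α_mom = ȳ²/(var(y) − ȳ)` clipped to a positive range. With thousands of
windows the conditionals are dominated by the data; the tests for the
conjugate updates use explicitly diffuse priors so the closed forms are
exact.

**Initialization** is deterministic given the seed: means at the
`(1..K)/(K+1)` sample quantiles, shared dispersion from sample moments,
transition diagonal 0.8 with the remainder split over the allowed
neighbours, path by nearest initial mean. Run lengths default to 1500
iterations / 20% burn-in for the normal family and 40000 / 12.5% for
counts (count fits mix more slowly because of the latent intensities and
the Metropolis shape step, whose acceptance rate is ~0.1–0.3 at genome
lengths).

A single RNG stream, seeded once per run, drives every draw in a fixed
documented order, so identical seeds give bit-identical results.

## Numerical choices

- Forward messages are renormalised at every position and the log scaling
  factors accumulated (natural logs); the per-position scaling record is
  returned as a numerical audit. This is stable for L in the millions.
- Positions with `-inf` log density in *every* state raise an error
  rather than being skipped; dropped/masked windows must be removed
  upstream (the track machinery does this and records the gap positions).
- Emission log densities are shifted by their per-row maximum before
  exponentiation.
- The forward/backward/path scans are numba-compiled; everything around
  them is vectorised numpy.
- Stationary distributions come from a dense linear solve; clipped at
  zero and renormalised to absorb solver round-off.

## Diagnostics

- **Autocorrelation screen**: the variance of consecutive-window
  differences is compared with the median of the same statistic over
  random permutations (25 by default; the median stabilises the null).
  Two p-values are reported. The parametric one-sided F-test with
  (L−2, L−2) degrees of freedom reproduces the extreme significance
  levels customarily quoted for genome tracks, but it is *conservative*
  under the null, because the observed and permuted variances derive from
  the same data values and their ratio is under-dispersed relative to an
  F distribution. The empirical permutation p-value
  `(1 + #{var_perm ≤ var_obs})/(n+1)` is exactly calibrated under
  exchangeability (type-I error ≈ 1/(n+1) granularity) and is the one to
  use near the decision boundary. Constant sequences are reported with a
  degeneracy flag.
- **Adjacent-state separation**: one-sided Welch t-tests (normal family)
  on the observations hard-assigned to neighbouring states; for counts, a
  "Poisson rate test" is needed but not uniquely defined in common usage,
  so the exact conditional binomial test is used: given the combined
  total of two states, the higher state's total is Binomial with success
  probability proportional to its window count. States with fewer than
  two windows are flagged untestable.
- **Model selection**: mean and median retained log-likelihood per K
  (their gap indicates autocorrelated traces), plus an advisory flag on
  the smallest K whose incremental mean-log-likelihood gain is below 10%
  of the previous increment while all adjacent-state tests are
  significant. The choice of K is never automated — the table is the
  deliverable.
- **Fit quality**: observed vs fitted mixture density (occupancy-weighted
  state densities), means ± 1 sd bands, QQ pairs at 199 evenly spaced
  probabilities with the mixture quantile obtained by monotone bisection
  of the mixture CDF; for counts, a hanging rootogram
  (`√expected − √observed` per count value).
- **Annotation comparison**: hard-state cross-tabulation, Spearman
  correlation of the position posterior-mean tracks, and a rolling
  Spearman series (default width 40 windows) for screening anomalous
  regions.

## Window tracks

Coordinates are 0-based half-open throughout. Chromosomes are tiled with
non-overlapping fixed-size windows; a trailing partial window is
*dropped*, not truncated, so exposure is constant across windows (both
emission families assume this). GC proportion uses called bases (A/C/G/T,
case-insensitive; soft-masked lowercase counts as called) as the
denominator; windows below the called-fraction threshold (default 90%)
are dropped. Feature counting (gene density) increments every window an
interval overlaps by ≥ 1 bp, so boundary-spanning features count in
multiple windows; read aggregation assigns each interval to exactly one
window by its leftmost coordinate, so totals are conserved. Exclusion
masks (e.g. centromere/telomere-adjacent regions, which have their own
dynamics) must be supplied by the user as BED; masking is idempotent.
Dropped and masked windows are removed from the sequence handed to the
HMM and the remaining windows are treated as contiguous; window
coordinates are retained so annotations map back to true positions.

## What the simulator covers — and what it does not

The simulator draws from exactly the model above (stationary start,
tridiagonal chain, normal or gamma-Poisson emissions, ground truth
retained including latent intensities). Passing recovery tests therefore
demonstrates the *sampler's* correctness and the information content of
tracks of the tested length — not robustness to real-data violations:
state-specific variances (real GC tracks are more variable at high GC),
overdispersion beyond gamma-Poisson, mappability artefacts, or missing
windows breaking contiguity. With heterogeneous true variances the shared
dispersion assumption biases state means predictably or merges states;
this is inherent to the model class.

## Test and validation design

Tolerance and size choices in the test suite: the forward–backward
recursions are checked against exhaustive path enumeration (instances
with `K^L ≤ 4096`) at 1e-12; reversibility of 1000 random tridiagonal
matrices at 1e-10; conjugate updates against closed forms within 3
Monte-Carlo standard errors at 1e4 draws. Full-sampler recovery runs use
L = 4096 with K = 3 (normal: means 0/1/2, σ = 0.3, 1000 iterations;
counts: α = 2, rates 4/1/0.25, 4000 iterations). At these conditions the
shape α is weakly identified: a direct numerical MLE of the exact
marginal likelihood deviates from the truth by several percent on
individual realisations, so recovery tolerances of ~10% on α and the
state means are near the information limit rather than comfortable
margins. Model-selection behaviour is exercised on 20 replicate
three-state datasets of L = 1024 with 300-iteration fits per K — the
plateau pattern it checks is scale-free, so moderate run sizes suffice.

## Limitations

- No Viterbi decoding: annotation is by marginal posteriors, which is
  what downstream correlation analyses consume.
- No order-constrained (truncated) conditionals: ordering is enforced by
  relabelling, which mixes well here; a truncated-conditional variant
  would be a drop-in alternative behind the same interface.
- No BAM parsing (convert alignments to BED first), no liftover, no
  automatic centromere/telomere detection.
- Exposure per window is fixed at 1 (counts are per-window totals); no
  offset term for variable mappable length.
- Formal model-selection criteria (AIC/BIC/DIC) are deliberately not
  reported; none is well established for HMMs with this structure.
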