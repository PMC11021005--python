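# ohmmed

Ordered hidden Markov models with convex emission densities, for
segmenting autocorrelated genomic tracks.

Genomic features such as base composition, gene density, or windowed
ATAC/ChIP read counts vary continuously and slowly along chromosomes:
neighbouring windows look alike, and transitions from high to low levels
pass through intermediate ones. `ohmmed` models such a track as a hidden
Markov chain over *K* states that are totally ordered by the means of
their emission distributions, with transitions allowed only between
order-neighbours. It infers the number-of-states diagnostics, the state
parameters, the transition rates, and a per-window probabilistic
annotation. Intended users are genomicists and statistical
bioinformaticians who want an assumption-light segmentation of windowed
tracks (GC proportion, gene counts, epigenetic mark counts) into
statistically distinguishable levels.

## Model

Windows `l = 1..L` carry observations `y_l` driven by hidden states
`θ_l ∈ {1..K}`:

- **Normal family** (real-valued tracks, e.g. GC proportion):
  `y_l | θ_l = i ~ N(μ_i, σ²)` with a *shared* standard deviation σ and
  strictly increasing means `μ_1 < … < μ_K`.
- **Gamma-Poisson family** (count tracks, e.g. genes or reads per
  window): a latent intensity `λ_l | θ_l = i ~ Gamma(α, β_i)` (shared
  shape α, strictly decreasing rates `β_1 > … > β_K`), then
  `y_l ~ Poisson(λ_l)`; the marginal count law per state is negative
  binomial with mean `α/β_i`.

Sharing the dispersion parameter makes the log-likelihood-ratio between
any two states monotone in `y`, which is what defines the total ordering
of states and eliminates MCMC label switching. Transitions are restricted
to order-neighbours, so the transition matrix **T** is tridiagonal; the
initial distribution is the stationary distribution π of **T**, which
makes the hidden chain reversible (detailed balance `π_i T_ij = π_j T_ji`)
and leaves only `3K − 1` free parameters versus `K(K+2) − 1` for an
unconstrained HMM.

Inference is a Gibbs sampler: each sweep draws a full hidden path by
forward-filtering backward-sampling, updates the emission parameters from
their conjugate conditionals (plus a Metropolis step on log α for
counts), restores the ascending-mean labelling by a joint relabelling
sort, and redraws the tridiagonal rows from Dirichlet conditionals.
The scaled forward–backward recursions are jit-compiled and handle
chromosome-scale tracks (run time is linear in L).

## Worked example

Simulate a GC-like track from a 3-state model, screen it for
autocorrelation, and re-fit it:

```python
import numpy as np
import ohmmed as oh

P = oh.TransitionMatrix(np.array([
    [0.95, 0.05, 0.00],
    [0.05, 0.90, 0.05],
    [0.00, 0.10, 0.90],
]))
params = oh.NormalEmissionParams(means=np.array([0.38, 0.45, 0.55]), sd=0.03)
sim = oh.simulate_sequence(P, params, 2000, seed=4)

rep = oh.autocorrelation_check(sim.y, seed=0)
cfg = oh.MCMCConfig(n_iter=1500, K=3, family="normal", burnin_fraction=0.2, seed=0)
fit, trace = oh.run_mcmc(sim.y, 3, config=cfg)
```

This prints (via the statements in the full example):

```
autocorrelation screen: F = 0.253, p = 1.46e-193 (permutation p = 0.038)
posterior mean state means: [0.3784 0.4485 0.5515]
posterior mean shared sd:   0.0305
occupancy: [0.39  0.414 0.196]
mean run length per state: [21.1 11.  10.3]
posterior mean transition matrix:
[[0.946 0.054 0.   ]
 [0.051 0.902 0.047]
 [0.    0.099 0.901]]
assignment accuracy vs truth: 0.97
```

The screen's F statistic far below 1 says consecutive windows differ much
less than randomly ordered ones — the autocorrelation the model assumes.
The fit recovers the three state means (truth 0.38/0.45/0.55), the shared
sd (truth 0.03) and the sticky transition structure; `fit.gamma_mean`
holds per-window state probabilities, `fit.hard_assignment` the
most-probable state, and `fit.posterior_mean_track` the smoothed value
track used for cross-feature correlations
(`oh.neighbor_mean_significance` confirms that adjacent state means are
statistically separated).

The same workflow is available from the shell:

```sh
ohmmed simulate --family normal --length 2000 --seed 4 --params params.json --out track.tsv
ohmmed check-autocorr --track track.tsv --out screen.tsv
ohmmed fit --track track.tsv --family normal --K 2..5 --iter 1500 --burnin 0.2 \
           --seed 0 --out-prefix run
ohmmed diagnose --track track.tsv --summary run.K3.summary.json \
                --annotation run.K3.annotation.tsv --out-prefix diag
```

`fit` with a K range also writes a model-selection table (mean/median
log-likelihood per K with a plateau suggestion). `gc-windows` and
`count-windows` build tracks from FASTA and BED/GFF3 inputs;
`compare` cross-tabulates two annotations and reports the Spearman
correlation of their posterior-mean tracks.

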