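# Methods

## Model

treesweep computes an approximate full likelihood for the additive selection
coefficient `s` acting on a focal biallelic site, given one or more labeled
local genealogies at that site. The model has two latent layers:

1. **The allele-frequency trajectory** `X(t)`: the population frequency of
   the derived allele, backward in time from the present. It follows a
   Wright–Fisher diffusion with additive (genic) selection — the per-
   generation deterministic update is `x → x + s·x(1−x)/(1+2sx)` and the
   sampling variance is `x(1−x)/(2N)` — discretized onto a frequency grid and
   onto epochs of a time grid. State 0 (the allele does not yet exist) is
   absorbing backward in time: hitting it is the origination of the mutation.
2. **The genealogy**, summarized by lineage counts: under the structured
   coalescent, while the derived allele segregates, lineages coalesce only
   within their allelic class, the derived class of size `N·x` and the
   ancestral class of size `N·(1−x)` (pairwise rate `1/(2z)` per generation
   for class size `z` diploids). Older than the mutation, the surviving
   lineages (ancestral survivors plus the single derived root lineage) form
   one mixed class of size `N`.

Both layers are observed only at the `K+1` boundaries of the time grid. The
number of lineages surviving an epoch follows Tavaré's exact lines-of-descent
distribution; where its alternating sum is unstable (large counts, very large
`z/Δt`) a bin-integrated normal approximation with mean `2η/Δτ` is used
(automatic switch at start count > 40 or `z/Δt > 10⁴`, plus a cancellation
fallback at 10 orders of magnitude).

Because by exchangeability the likelihood of a labeled tree depends on the
topology only through these per-class counts, each genealogy reduces to a
count series (derived / ancestral / mixed counts at each grid time, in the
conventions of the companion table reproduced in the tests). The hidden
trajectory is marginalized by forward–backward recursions of a
time-inhomogeneous HMM whose emissions are the lines-of-descent transition
probabilities evaluated at each candidate frequency, with two coupling rules:

* the absent state (`x = 0`) is admissible in an epoch only if the derived
  class has already collapsed to its single root lineage (`c_der = 1`), since
  the mutation must fall on one branch;
* the terminal boundary puts all mass on `x = 0` with full coalescence — the
  allele must have originated, and the sample coalesced, by the horizon.

The likelihood ratio surface over candidate selection models is the
importance-sampling average `LR(s) = (1/M) Σ_m P(C_m|s)/P(C_m|0)` over trees
sampled under the neutral posterior (or true trees, for which `M = 1` per
replicate). Emissions do not depend on `s`, so each tree's emission matrix is
computed once and reused across the whole surface. The per-point effective
sample size `(ΣΩ)²/ΣΩ²` is reported, with a warning below 5% of `M`.

The sweep-from-standing-variation (SSV) model makes `s` a step function:
`s(t) = s` for `t ≤ t_s`, `0` earlier. The soft-vs-hard statistic is
`log max_{s,t_s} LR − log max_s LR(t_s = ∞)`, non-negative by nesting.
Trajectory estimates are importance-weighted mixtures of per-tree posterior
marginals (mean and 25–75% band per epoch), at the MLE by default or averaged
over `s` under a uniform prior with trapezoid weights.

## Discretization choices

* **Frequency grid** (`d` bins): `{0}` plus `d−1` interior points at
  Beta(½,½) quantiles, `x_j = sin²(πj/2d)` — denser near the boundaries,
  where trajectory resolution matters. 1 is excluded so a segregating allele
  has a single absorbing state; mass drifting above the top bin is held
  there. Default `d = 200` for single-site inference; the validation
  experiments use `d = 100`, which halves runtime at no measurable cost in
  estimator bias at the sample sizes studied.
* **Time grid**: log-spaced boundaries from 10 generations to the horizon
  `100 × 2·max(N)` (finer recently, where most selection signal lives), with
  `K = 32` epochs by default; candidate onset times are inserted as extra
  boundaries so SSV epochs stay internally homogeneous.
* **Blocked Wright–Fisher kernels.** On a `d ≈ 100` grid a one-generation
  Gaussian kernel is much narrower than a bin and the discretized chain
  misrepresents the diffusion. Kernels are therefore built over blocks of
  `τ ≈ 2·2Nπ²/d²` generations (for the Beta-quantile grid this makes the
  block standard deviation ≈ √2 bin widths uniformly), capped at `τ ≤ 1/s`
  so drift never leaps over bins; the block mean follows the deterministic
  selection map and the variance accumulates along that path. Epoch kernels
  are compositions of blocks via binary matrix squaring.
* **Time reversal.** The backward (into-the-past) kernel is the reversal of
  the forward block kernel under a reference measure π: the classic neutral
  sojourn measure of a new mutant, `π(x)dx = 2dx/x` generations, with unit
  mass at 0, and mutants entering at the lowest interior bin (diffused for
  half a block). Under this measure the per-generation mutation flux cancels
  between forward entry probability and interior sojourn mass, so the
  origination (backward absorption) probabilities are flux-independent and
  parameter-free. A uniform reference is available as a sensitivity switch.
  We reverse each block and compose the reversed blocks (rather than
  reversing the composed epoch kernel); the two differ only by the degree to
  which π fails to be invariant, and this ordering makes the HMM's trajectory
  prior *exactly* the law of the chain the simulator samples.
* **Initialization.** The present-day frequency distribution is the binomial
  likelihood of the observed derived/ancestral sample counts times π,
  normalized — the stationary-distribution factor for the frequency itself is
  deliberately not part of the likelihood ratio in `s`.
* **Recursions** run in log space with per-epoch max-rescaling; `log LR(0)`
  is exactly 0 by construction. Models whose trajectory prior cannot reach a
  deep derived MRCA within double precision get likelihood `−inf` (they are
  impossible for that tree), which simply removes them from the surface.
* **MLE.** Grid argmax (31-point log grid on `[10⁻⁴, 0.5]` plus 0 by
  default), refined by golden-section search between the neighboring grid
  points for 1-D surfaces; ties break toward the null. 2-D (s, t_s) surfaces
  report the grid argmax.

## The simulator and what it does (not) emulate

`simulate_trajectory` samples the *same* time-reversed Wright–Fisher chain
whose composition is the HMM prior, at block resolution, starting from the
conditioned present-day frequency until origination; for time-varying `N`,
whole trajectories are rejected with probability `1 − N(t_origin)/max N`,
implementing the linear scaling of mutational influx with population size.
`simulate_genealogy` draws per-epoch lines-of-descent transitions for the
derived and ancestral classes given the trajectory, places coalescence times
uniformly within epochs, requires the derived class to reach its single root
lineage by the end of the origination epoch (joint resimulation otherwise,
with rejection counts reported), and then coalesces the mixed class. The
returned count series is exact for the returned tree (a round-trip identity
tested against `extract_counts`).

Because generator and inference share the Wright–Fisher discretization and
the lines-of-descent family, the validation experiments test the estimator
(marginalization, importance weighting, maximization, calibration) under its
own generative model — the appropriate target for parameter-recovery and
power claims. They do **not** exercise: tree-inference error (true trees
stand in for posterior ARG samples, which can only make power and accuracy
optimistic relative to sampled trees), recombination along the sequence,
haplotype-level noise, dominance, recurrent mutation, or population
structure. Ancient samples are supported in the count bookkeeping (leaves
enter their class at their own age) but their effect on power is not
separately studied.

The European-like demography is a Tennessen-style piecewise-constant model
(per-epoch harmonic means; explosive recent growth to ~1.6×10⁵, a bottleneck
of ~1.9×10³ at 920–2040 generations, ancestral sizes 1.4×10⁴/7.3×10³),
stored as a versioned TSV fixture.

## Study designs

* **Equilibrium design**: constant `N = 10⁴`, 25 diploids (50 lineages),
  derived frequency 75% today (38/12 sampled lineages), hard sweeps with
  `s ∈ {0, 0.003, 0.01}`, 100 replicates each, `d = 100`, `K = 32`.
  Significance is always against the matched neutral null (same demography,
  sample size, and present-day frequency) at its empirical 1% quantile.
* **Standing-variation design**: European-like demography, 50 diploids
  (100 lineages), frequency 50% today, onset 100 generations ago,
  `s ∈ {0.01, 0.03}`, each with a matched hard-sweep null of the same
  strength; 2-D surface over 12 `s` values × onsets
  {50, 100, 200, 500, 1000, ∞}.

These problem sizes run the full validation (1100 replicates) in a few
minutes on one CPU; they are the package's chosen desk-scale conditions.

## Known limitations

* The reversal-under-π trajectory prior is an approximation to the exact
  conditioned diffusion; π is the neutral sojourn measure even when `s > 0`
  (selection enters through the forward kernel being reversed). Parameter
  recovery in the experiments is the arbiter of its adequacy.
* Near-boundary dynamics are resolved only to the lowest interior bin
  (`x₁ ≈ (π/2d)²`), so origination-time detail below that frequency is at
  grid resolution.
* With a single epoch (`K = 1`) the model is degenerate — the allele must
  both segregate and have originated — and the likelihood is identically
  zero; at least two epochs are required.
* Likelihoods assume the input tree's branch lengths are in generations and
  correct; no branch-length re-estimation is attempted.
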