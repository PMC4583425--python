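# Methods

## Model

Each candidate site contributes an L-bp window of per-base cut counts per
replicate, L = 2^J (default 64, so J = 6). The per-base Poisson rate
vector is reparameterized into a total rate λ₀ and dyadic split
probabilities p_jk — scale 1 splits the window in half, scale J splits
adjacent base pairs. Two properties make this useful: the Poisson
likelihood factorizes *exactly* into a Poisson term for the total and one
binomial term per split (`multiscale.factorized_poisson_loglik` asserts
the identity to 1e-9 against the per-base product, and the test suite
treats it as the central correctness oracle), and spatially smooth
differences between cleavage profiles concentrate in few split
parameters, so heterogeneity can be modeled scale by scale.

A per-site latent Z (bound/unbound) mixes two generative hierarchies:

- bound: λ₀ ~ Gamma(α_s, α_s/λ̄₀_s) per replicate s (negative-binomial
  totals, mean λ̄₀_s, variance λ̄₀_s + λ̄₀_s²/α_s) and
  p_jk ~ Beta(p̄_jk τ_j, (1−p̄_jk) τ_j) (beta-binomial splits). (p̄, τ) are
  shared across replicates; scale-0 hyperparameters are replicate-specific
  so library depth never masquerades as biology.
- unbound: its own gamma-Poisson totals; splits are the constant ½
  (uniform reads), or Beta(p̄ᵒτᵒ, (1−p̄ᵒ)τᵒ) when the flexible background
  is enabled.

The mixing weight ζ_n is a logistic function of site features (intercept
plus PWM score or other covariates). Posterior odds
P(Z=1|X)/P(Z=0|X) are the binding score; log odds and posterior
probability are reported per site.

Assumptions worth stating plainly: replicates and sites are independent
given Z (no site-level random effect shared across replicates); counts in
a window come from one homogeneous component (no partial occupancy
states); the window is small enough that one motif dominates it; and all
heterogeneity in shape is captured by scale-wise precisions, not by
position-specific variances.

### Unimodality constraint

The betas are constrained unimodal: p̄_jk τ_j ≥ 1 and (1−p̄_jk) τ_j ≥ 1.
Without it the splits can go U-shaped and the "mean profile" stops meaning
anything. The constraint is enforced at construction of any parameter set
(τ_j is projected up to the floor plus a 1e-6 margin), not only inside the
optimizer, so user-supplied parameter sets satisfy the invariant too.

### Limits and special cases

τ_j → ∞ removes shape heterogeneity and recovers the classical
fixed-profile (negative-binomial total × binomial splits, i.e.
multinomial-profile) footprint model; the package checks convergence of
the likelihood to that limit at τ ∈ {1e2, 1e4, 1e6}. The `total_only`
variant keeps only the scale-0 terms ("no cleavage profile") and is the
ablation used to quantify how much the profile itself contributes.

## Fitting

Because totals and splits marginalize in closed form, the only latent
variable is Z and exact EM applies:

- E-step: posterior q_n by Bayes' rule in log space (log-sum-exp); sites
  where both components are −inf fall back to the prior with a warning.
- M-step: block maximization of the q-weighted log-likelihood with
  analytic gradients (digamma forms), L-BFGS-B per block in an
  unconstrained parameterization — log for α and λ̄₀, logit for p̄, and
  τ_j = floor(p̄_j) + exp(s_j) so the unimodal set stays open. Each block
  reverts to its previous value if the optimizer fails to improve it, so
  the marginal likelihood is non-decreasing by construction. Blocks:
  (α_s, λ̄₀_s) per replicate per component, and (p̄_j, τ_j) per scale.
- prior update: ridge-stabilized (1e-6) Newton logistic regression with
  fractional responses q_n; the ridge keeps perfect separation finite.

One EM cycle is treated as a fixed-point map on the packed unconstrained
vector and accelerated with SQUAREM: steplength −‖r‖/‖v‖ with
backtracking toward −1 (the plain EM step) whenever the extrapolated
point does not improve the objective, followed by one stabilizing map
application. Extrapolated points are saturated (clipped logits/logs)
before evaluation so a wild step degrades the objective instead of
raising. Plain EM is available (`accelerate=False`) and the two reach the
same fixed point; the test suite requires agreement to 1e-3 per packed
parameter.

M-step objectives are evaluated on the unique (parent, left) count pairs
per node with posterior-summed weights — an exact aggregation that cuts
special-function work by an order of magnitude and is what keeps a
5000-site, 2-replicate, 64-bp fit in the low seconds.

Defaults: tol 1e-6 on the relative log-likelihood change, 200 outer
iterations, 25 L-BFGS iterations per block. Initialization is
moment-style and deterministic: ζ = 0.5; bound/unbound λ̄₀ from the
top/bottom quartile mean totals per replicate; α = 1; p̄ at pooled
empirical split fractions clipped to [0.01, 0.99]; τ_j = 100. After
fitting, if the "bound" component ended up with the smaller mean total,
labels are swapped and the prior negated (bound sites are hypersensitive;
the mixture alone does not fix the orientation).

Degenerate sites with zero counts in all replicates are retained — they
contribute only scale-0 terms (a zero-count parent contributes exactly 0
to any split likelihood), and dropping them would bias the background
mean.

### Flexible background

With naked-DNA counts at the same sites, fitting is two-stage: stage 1
maximizes the beta-binomial split likelihood of the naked-DNA data with
every site treated as background (no mixture) to get (p̄ᵒ, τᵒ); stage 2
runs the mixture EM on the chromatin data with those parameters frozen
(they are never packed into the optimization vector, so they pass through
bit-identically). Estimating the background profile from chromatin data
itself is deliberately not offered: the background precision gets
underestimated and false positives rise, so the variant requires the
naked-DNA input and says so.

## Synthetic data

`simulate.simulate_dataset` samples the hierarchy forward: Z, then per
replicate the gamma rate, the Poisson total, and binomial thinning down
the pyramid with beta-drawn (bound) or fixed/flexible (unbound) split
probabilities; leaf k is base pair k. The RNG draw order is fixed and
documented in the module docstring (the bound-component beta is always
drawn so the stream does not depend on Z), making seeds portable.

The canned fixtures define the package's reference study conditions
(1000 sites, 2 replicates, 64 bp, 40% bound unless overridden):

- `footprint_strong` — mean profile with hypersensitive shoulders, an
  80%-deep central dip and a slight left/right tilt; bound totals
  λ̄₀ = 20/replicate (α = 4) vs unbound 8 (α = 2); precisions smallest at
  medium scales (τ ≈ 32, 18, 11, 11, 18, 32 for J = 6), where real
  footprint data are most overdispersed.
- `footprint_weak` — 35%-deep dip, bound totals 12 vs 8.
- `no_footprint` — splits fixed at ½ with τ = 1e6 in both components;
  only totals differ, the ablation case.
- `heterogeneous_replicates` — 4-fold depth contrast between replicates
  (bound 40 vs 10, unbound 16 vs 4), the pooling-vs-separate contrast.

These values were chosen once as realistic desk-scale conditions (tens of
cuts per window at moderate sequencing depth, partially overlapping total
distributions so the profile carries real information) and are not tuned.

What the simulator does *not* emulate: mapping artifacts and mappability
gaps, sequence-dependent cleavage beyond the flexible-background split
means, fragment-length structure of paired-end data, correlated
neighboring sites, or site-level effects shared across replicates.
Passing tests therefore demonstrate correctness of the inference under
the model's own assumptions — not robustness to every artifact of real
libraries.

`split_ratio_diagnostic` reproduces the classic overdispersion check: the
per-site left-half/total ratio in the window against the same statistic
after resimulating each site's left count as Binomial(total, pooled
ratio). Heterogeneous data (small τ₁) show a variance ratio well above 1;
fixed-profile data sit at ≈ 1.

## Extraction and evaluation conventions

Single-end DNase reads count at their 5′ end (plus strand: leftmost
aligned base; minus: rightmost); ATAC reads get the +4/−5 Tn5 offset by
default. Windows are [mid − L/2, mid + L/2) around the motif midpoint,
0-based half-open; minus-strand motif windows are reversed so profiles
are motif-oriented. Mapping quality < 10 is skipped by default. An
optional strand-separated mode emits motif-strand and opposite-strand
cuts as two pseudo-replicates sharing p̄ — the likelihood is
replicate-agnostic, so no new machinery is needed.

Site filters follow standard practice: a PWM-score threshold applied
upstream (a helper flag re-filters the BED score column), and ≥ 80% of
window bases uniquely mappable when a mappability track is supplied (the
filter is skipped with an explicit warning otherwise).

The evaluation gold standard labels a site bound if it overlaps a ChIP
peak, unbound if it overlaps none *and* has fewer depth-normalized ChIP
than control reads in a 400-bp window, ambiguous otherwise (excluded from
AuROC). Depth normalization divides each count by its library size; the
400-bp window is anchored at the motif midpoint. AuROC is the rank-based
Mann-Whitney statistic with averaged ties.

## Numerical notes

All likelihoods are computed via log-gamma/log-beta; totals up to 1e6
stay finite. Zero-mass parents are the one genuinely degenerate case:
the forward transform flags their splits as undefined (nan), the inverse
maps them to zero subtrees, and n = 0 nodes contribute exactly 0 to every
likelihood — the only consistent limit. Windows must be a power of 2; no
padding is offered, since padding would distort edge splits. Posterior
probabilities are reported as expit(log odds), so the logit identity
holds exactly wherever the float is not saturated.

## Known limitations

- No site-level random effect shared across replicates, and no spatial
  smoothing prior on p̄ across positions — both were considered and left
  out to keep inference simple; with many sites p̄ is well estimated
  without smoothing.
- No k-mer-level modeling of sequence context beyond the flexible
  background's split means.
- Paired-end fragment lengths are ignored; only the transposition (or
  nick) base matters.
- Scale precisions at the finest scales are weakly identified when
  windows carry only a handful of cuts; their recovery is only reliable
  at scales with hundreds of informative counts.
- Peak calling and PWM scanning are upstream of this package: peaks and
  scored sites come in as files.
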