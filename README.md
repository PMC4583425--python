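# msfoot — multiscale footprint inference from chromatin accessibility

`msfoot` infers which candidate transcription-factor motif sites in a
genome are actually bound, using per-base DNase I cleavage counts
(DNase-seq) or Tn5 transposition counts (ATAC-seq) in a window around each
site. Bound sites leave a *footprint* — a local depression in cleavage
flanked by hypersensitive shoulders — but real footprints vary in shape
from site to site and from replicate to replicate. `msfoot` models that
heterogeneity explicitly instead of assuming one fixed cleavage profile.

It is intended for regulatory-genomics analysts who have a list of
PWM-scored motif matches and one or more accessibility libraries, and want
a posterior binding probability per site without ChIP-seq (ChIP-derived
labels are used only to evaluate accuracy).

## Model

For site *n*, replicate *s*, the window of length *L* = 2<sup>*J*</sup>
holds counts *X*<sup>*n,s*</sup> with per-base Poisson rates
*μ* = (*μ*₁, …, *μ*<sub>*L*</sub>). The rates are reparameterized into a
total intensity λ₀ = Σ*μ*<sub>ℓ</sub> and dyadic split probabilities
*p*<sub>*jk*</sub> (mass of the left child over its parent) at scales
*j* = 1…*J*, a one-to-one map under which the Poisson likelihood
factorizes exactly into Poisson(total | λ₀) × Π Binomial(left | parent,
*p*<sub>*jk*</sub>).

A latent indicator *Z*<sup>*n*</sup> marks binding, with logistic prior
ζ<sub>*n*</sub> on site features (PWM score, …). Conditional on *Z*:

- **bound**: λ₀ ~ Gamma(α<sup>*s*</sup>, α<sup>*s*</sup>/λ̄₀<sup>*s*</sup>)
  (marginally, a negative binomial total with mean λ̄₀<sup>*s*</sup> and
  variance λ̄₀ + λ̄₀²/α), and
  *p*<sub>*jk*</sub> ~ Beta(p̄<sub>*jk*</sub>τ<sub>*j*</sub>,
  (1 − p̄<sub>*jk*</sub>)τ<sub>*j*</sub>) (marginally beta-binomial splits).
  p̄ is the mean cleavage profile; the scale precisions τ<sub>*j*</sub>
  measure heterogeneity, constrained unimodal
  (p̄τ ≥ 1, (1 − p̄)τ ≥ 1). As τ → ∞ the model collapses to the classical
  fixed-profile (multinomial) footprint model.
- **unbound**: its own gamma-Poisson total and splits fixed at ½ (uniform
  reads), or — in the `multiscale_flexbg` variant — beta splits
  (p̄ᵒ, τᵒ) learned from naked-DNA DNase-seq to absorb sequence bias.

Replicates are independent given *Z*, sharing (p̄, τ) but with
replicate-specific scale-0 hyperparameters to absorb depth differences.
Because the site-level latents marginalize in closed form, the remaining
mixture is fit by exact EM with SQUAREM acceleration, and each site gets
posterior odds P(*Z* = 1 | *X*) / P(*Z* = 0 | *X*).

## Worked example

```python
import msfoot as mf

# a synthetic dataset with a strong footprint: 1000 sites x 2 replicates
# x 64 bp, 40% bound
data = mf.make_fixture("footprint_strong", seed=21)

est = mf.FootprintMixture().fit(data.counts)
print(f"converged after {est.n_iter_} iterations: "
      f"loglik {est.loglik_trajectory_[-1]:.1f}")
odds = est.decision_function(data.counts)        # natural-log posterior odds
auroc = mf.compute_auroc(odds, data.z_true)
print(f"AuROC against simulated truth: {auroc:.3f}")
print("fitted mean totals, bound vs unbound:",
      est.bound_.lambda0_bar.round(1), est.unbound_.lambda0_bar_o.round(1))
```

prints

```
converged after 3 iterations: loglik -64659.0
AuROC against simulated truth: 0.970
fitted mean totals, bound vs unbound: [21.1 19.4] [7.8 8.2]
```

i.e. the bound component is recovered as the hypersensitive one (~20 vs ~8
expected cuts per replicate window) and ranking sites by posterior odds
recovers the simulated binding labels with AuROC 0.97.

The same workflow runs from the shell on BED sites plus BAM alignments
(or exported count tables):

```bash
msfoot simulate --profile footprint_strong --n-sites 300 --seed 3 --out-prefix sim
msfoot learn --sites sim.sites.bed --counts sim.counts.rep0.tsv \
             --counts sim.counts.rep1.tsv --model-out model.json
msfoot infer --sites sim.sites.bed --counts sim.counts.rep0.tsv \
             --counts sim.counts.rep1.tsv --model model.json --out posterior.bed
msfoot evaluate --posterior posterior.bed --truth sim.truth.tsv
```

## Layout

- `msfoot.multiscale` — dyadic reparameterization, count pyramids, exact
  factorized Poisson likelihood
- `msfoot.likelihoods` — negative-binomial / beta-binomial marginals and
  the component parameter sets (JSON-serializable)
- `msfoot.inference` — EM engine, SQUAREM, logistic prior, flexible
  background, posterior odds
- `msfoot.estimator` — the `FootprintMixture` sklearn-style estimator
- `msfoot.simulate` — the generative sampler, canned fixtures and the
  overdispersion diagnostic
- `msfoot.io_eval` — BAM/BED extraction, site filters, ChIP gold standard,
  AuROC
- `msfoot.cli` — `msfoot simulate | learn | infer | evaluate`

See `docs/methods.md` for modeling assumptions, defaults and limitations.
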