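# Methods

`microherit` estimates, for integer-transformed microbial traits measured on a
pedigreed population, the fractions of phenotypic variance due to additive
genetics (h²), the birth litter (l²) and the housing cage (c²), tests each
fraction against zero with Savage–Dickey Bayes factors, and chooses between a
Gaussian and a zero-inflated Poisson data model by DIC. This note documents the
models, the priors, the samplers, the numerical choices, and what the synthetic
studies used in the test suite do and do not establish.

## Models

**Linear mixed model (LMM).** For a trait vector `y` on `n` animals,

    y | β, V ~ MVN(X β, V),
    V = σ²_P [ K_A h² + K_L l² + K_C c² + I (1 − h² − l² − c²) ],

where `X` carries the systematic factors (farm/diet/regime group, batch,
weaning-weight class), `K_A = Z_A A Z_A'` is the observation-level additive
kernel from the numerator relationship matrix `A`, and `K_L = Z_L Z_L'`,
`K_C = Z_C Z_C'` are the 0/1 litter and cage block kernels. The model is
parameterized directly on the variance *ratios*, so each random effect is
integrated out rather than sampled: this is what makes a null value of a ratio
an interior point of the parameter space and a Savage–Dickey test possible.

**Zero-inflated Poisson (ZIP) mixed model.** A count `y_i` is a structural
zero with probability `p`, otherwise Poisson with mean `λ_i`. On the working
scales `λ*_i = log λ_i` and `p* = logit p`, the likelihood marginalizes the
zero indicators:

    ∏_{y_i=0} (1+e^{p*})⁻¹ (e^{p*} + e^{−exp(λ*_i)})
    × ∏_{y_i>0} (1+e^{p*})⁻¹ e^{−exp(λ*_i) + λ*_i y_i} / y_i! ,

and the second stage places the same Gaussian animal model on `λ*`:
`λ* ~ MVN(X β, V)`. The structural-zero indicators are never augmented; all
data-level updates work on the marginalized form.

## Priors

* `(h², l², c²)`: jointly uniform with density 6 on the unit simplex
  `{r ≥ 0, Σ r ≤ 1}`. Each marginal is then Beta(1,3) = 3(1−r)², equal to 3 at
  r = 0 — the prior ordinate used by every Bayes factor.
* `σ²_P`: flat on the positive reals. This prior is improper; with `n` of a
  few hundred the posterior is proper in practice, but the package does not
  verify propriety for degenerate designs (a single observation, a kernel that
  spans the data exactly).
* `β`: flat. `p*`: uniform on [−5, 5] (p between 0.0067 and 0.9933).

## Samplers

Both models run a single Metropolis-within-Gibbs chain; the default layout is
10,000 iterations with the first 1,000 discarded and no thinning.

The Gaussian stage (shared verbatim between the LMM, where the data are `y`,
and the ZIP second stage, where the "data" are the current `λ*`):

1. `β` — Gibbs draw from MVN((X'V⁻¹X)⁻¹X'V⁻¹w, (X'V⁻¹X)⁻¹).
2. `σ²_P` — Gibbs draw from the inverse-gamma(n/2 − 1, S/2) implied by the
   flat prior, `S = (w−Xβ)' K⁻¹ (w−Xβ)` with `K` the bracketed kernel.
3. each ratio in the fixed order h² → l² → c² — one reflected Gaussian
   random-walk Metropolis try on `[0, 1 − (sum of the other two)]`; the flat
   simplex prior cancels, so acceptance is the Gaussian likelihood ratio.

ZIP adds, before the Gaussian stage, an elementwise Metropolis sweep over all
`λ*_i` (target: the observation's ZIP data term times the conditional normal
of `λ*_i` given `λ*_{−i}`, computed from the precision matrix `V⁻¹` built once
per iteration) and a reflected random-walk update of `p*` inside [−5, 5].
`λ*` is initialized at `log(y_i + 0.5)` for positive records and `log 0.5` for
zeros; `p*` at the logit of the observed zero fraction (clipped).

Proposal steps default to 0.05 (ratios), 0.3 (`λ*`), 0.5 (`p*`) and adapt
toward a 20–45% acceptance rate during burn-in only, then freeze — adapting
during kept samples would bias the ordinate average below. Chains are
deterministic given the seed.

## Bayes factors

For each free ratio the sampler stores, per kept iteration, the normalized
conditional density of that ratio at zero given the current draws of
everything else. The conditional is known up to a constant on its support
`[0, 1 − other two]` and is zero beyond it, so normalizing over the support is
normalization over [0, 1]; the integral uses Simpson's rule on a fixed
129-point grid (halving the grid moves BFs by well under 1% in tests). The
per-iteration log ordinates are averaged with a max-shift (log-sum-exp), and

    BF = 3 / (averaged posterior ordinate at 0),

3 being the Beta(1,3) prior ordinate. Evidence classes: BF < 3.2 none,
3.2–10 substantial, 10–100 strong, ≥ 100 decisive; 1/BF > 3.2 flags support
for the *null*. A reduced model that pins the other ratios at zero has a
uniform conditional prior on the remaining ratio, so its Savage–Dickey prior
ordinate is 1, not 3; `compute_bf` takes it as an argument.

Two implementation notes. First, evaluating the conditional on a grid
requires the Gaussian likelihood at many values of one ratio with the rest
fixed; writing `K(r) = M + r Δ` and eigendecomposing `L⁻¹ Δ L⁻ᵀ` (Cholesky
`M = L L'`) makes every grid point O(n) after one O(n³) factorization, which
also serves that ratio's Metropolis step. This is exact, not an
approximation. Second, the ordinate can be evaluated on an iteration stride
(`bf_stride`) rather than every iteration; the subsampled average is an
unbiased Monte-Carlo estimator of the same quantity with somewhat higher
variance, and the test batteries use strides of 5–10 to keep their runtime
proportionate.

## DIC and model choice

DIC = D̄ + pD with pD = D̄ − D(θ̄). The focus is conditional: for the LMM the
deviance is −2 log MVN(y | Xβ, V) and θ̄ the posterior means of (β, ratios,
σ²_P); for the ZIP it is −2 log ZIP(y | λ*, p*) and θ̄ the posterior means of
(λ*, p*). The two models are compared at face value — a continuous density for
the LMM against a probability mass function for the ZIP, at different
conditioning levels (V integrated out versus conditional on λ*). That literal
comparison is deliberate: it is how this class of analyses applies DIC in
practice, and the cross-family, cross-focus caveat is a known conceptual
limitation that this package documents rather than repairs. In practice it produces the expected pattern:
traits dominated by zeros are won by the ZIP model, abundant traits whose
dispersion is at or below the Poisson level by the LMM.

Convergence is monitored with the Geweke z-score (first 10% vs last 50% of
each ratio chain), with segment variances from a Bartlett-tapered lag window
covering 4% of the segment. The estimator is validated against the AR(1)
closed form σ²/(1−φ)² and a KS test of the null z distribution.

## Integer transformation and trait filtering

Genus relative abundances and alpha-diversity indices are standardized
(sample sd, n−1) then multiplied by 100 and rounded half-away-from-zero;
CSS-normalized OTU abundances are only scaled and rounded, and must be
non-negative. Standardized traits necessarily contain negative integers, and
how such values could enter a Poisson likelihood is undefined; the package
therefore refuses to fit the ZIP model to any trait with negative values and
records the reason in the per-trait report (the LMM is always fitted). Traits
with a nonzero fraction below 5% are excluded up front; the rest are binned
into the frequency classes [5,10], (10,25], (25,50], (50,75], (75,100]
percent.

## Synthetic studies

The generator emulates the design the analysis assumes, with known truth for
recovery tests:

* **Pedigree** — founders plus `n_generations` of random matings; every
  female of a generation produces one litter and sires are drawn with
  replacement, giving paternal half-sib families. The final (phenotyped)
  generation has litters of `observed_litter_size` (default 2 — commercial
  rabbit studies phenotype a couple of kits per litter, and it is precisely
  the cross-litter pedigree links that let h² be separated from l²).
  Defaults (128 founders, 2 generations, litters of 4, observed litters of 2)
  give ~512 phenotyped kits from ~256 litters, the scale of the emulated
  study (425 kits, 196 litters, 189 cages).
* **Breeding values** — gene dropping: founders N(0, σ²_a), offspring the
  parent average plus a Mendelian deviation with variance
  0.5 σ²_a (1 − (F_s + F_d)/2); Var(u) = A σ²_a by construction and is
  checked against an independent allele-dropping oracle.
* **Housing** — litters are the full-sib groups of the final generation;
  cages are filled to `cage_size` (default 8) with at most 2 kits of any
  litter per cage, matching the anti-confounding rule of the emulated design.
  Batch is assigned per litter; group and weight class per animal (6/5/2
  levels).
* **Traits** — Gaussian traits are `Xβ + u + litter + cage + residual` with
  component variances `σ²_P (h², l², c², 1−Σ)`, then the integer
  transformation. ZIP traits put the same sum (plus a baseline, default
  log 30, so exponential-scale means land in the 10–100 range where the
  Poisson part is informative) on `λ*`, and zero the result with probability
  `p`. Fixed effects default to modest sizes (|β| ≤ 0.5 σ_P) so ratio
  recovery is not confounded. A Gaussian "OTU" trait receives a positive
  abundance baseline (default 5 σ_P) and the rare residual negatives are
  clipped to zero before rounding.

What the synthetic tests show: that the samplers recover the generating
parameters of their own model, that the BF has the intended operating
characteristics around the 3.2 bound, and that DIC sorts sparse from dense
traits. What they do not show: robustness to real microbiome features the
generator omits — compositionality, CSS artifacts, overdispersion beyond the
lognormal-Poisson layer, maternal genetic effects distinct from the litter
environment, and misspecified pedigrees.

Problem sizes in the test batteries (n ≈ 500 and ≈ 300 observed animals,
chains of 600–700 kept draws, 10 seeds per condition) are chosen as the
smallest sizes at which the studied effects are identifiable at the stated
tolerances; the sampler itself defaults to the full 10,000-iteration layout.

## Degenerate inputs and tie-breaks

* A proposed ratio whose kernel leaves the covariance non-positive-definite
  (the simplex boundary) gets −∞ likelihood and is rejected.
* If the other two ratios sum to ≥ 1, the third is skipped for that
  iteration (probability-zero event in the interior).
* A DIC difference below 1e−9 is reported as a tie and falls to the LMM.
* Geweke on a zero-variance segment returns NaN rather than raising.
* The conditional-ordinate quadrature refuses an all-(−∞) grid (no finite
  density anywhere) and returns exactly 0 when only the origin vanishes.

## Known limitations

* Dense `A` and dense kernels: memory is O(n²) in pedigree size; fine to a
  few thousand animals, not for hundreds of thousands.
* Single-chain design: no R-hat; convergence claims rest on Geweke plus the
  quadrature cross-checks.
* The improper σ²_P prior and the literal LMM/ZIP DIC comparison are
  reproduced behaviors, with the caveats above.
* The ZIP model is restricted to non-negative traits (see the transformation
  section); standardized traits are analyzed with the LMM only.
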