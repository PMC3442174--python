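# Methods

## Model

Data per zygosity group are a 3-cell count vector `(y11, yd, y00)` of
twin pairs (both affected / discordant / both healthy), assumed to come
from complete, non-selective ascertainment (a population-based
registry).  The likelihood is the product of two multinomials sharing a
prevalence `π` and having separate dependence differences `δ^MZ`,
`δ^DZ`, where `δ = P(affected | co-twin affected) − P(affected |
co-twin healthy)`.  The implied concordance rate is `q = δ(1−π) + π`
and the cell probabilities are `p11 = πq`, `pd = 2π(1−q)`,
`p00 = 1 − p11 − pd`.

Modeling assumptions, all of which the synthetic-data generator
reproduces exactly and real registries may violate:

* twins within a pair are exchangeable (no birth-order effect), so the
  discordant cells can be collapsed;
* prevalence is identical in MZ twins, DZ twins and singletons;
* `δ^MZ`, `δ^DZ` and `π` are a priori independent apart from the
  admissibility constraint;
* pair counts are fixed by design (no ascertainment through disease
  status).

### Admissibility

Validity of the cell probabilities requires `q ∈ [max(0, 2−1/π), 1]`.
We enforce this full condition — every cell in [0, 1] — rather than
only the lower bound `δ > (π−1)/π` that keeps `p00` non-negative,
because for `π < 1/2` that inequality alone admits negative `q`.  The
constraint is enforced in exactly one place: the log posterior returns
−∞ at inadmissible points, which makes a Metropolis proposal there be
rejected (the chain stays put).  The transforms themselves are total
functions; `from_real` never raises on finite input.

### Priors

`π ~ Beta(α1, α2)`; each `δ` has a truncated scaled-Beta density
`∝ (1+δ)^{s1−1} (1−δ)^{s2−1}` on [−1, 1] restricted to the admissible
region.  All six shapes default to 1 (non-informative; the posterior is
then proportional to the likelihood).  A prevalence study with `n1`
cases among `n1+n2` people gives `π ~ Beta(1+n1, 1+n2)` — the binomial
likelihood of that study folded into the flat prior.  A historical twin
study is pooled by summing count vectors per zygosity, which with flat
priors is algebraically identical to using its posterior as the new
prior (log likelihoods are additive in the counts; the test suite
asserts this identity exactly).  Unequal (power-prior) study weights
are deliberately not implemented; the API stub raises
`NotImplementedError`.

## Estimation

Sampling happens on the real line: `λ = ln(π/(1−π))`,
`μ = ln((1+δ)/(1−δ))`, with the change-of-variables Jacobian factors
`e^x/(1+e^x)²` included in the target density (multiplicative constants
dropped throughout).  Log-density evaluation is done in log space with
no epsilon clamping — the rare-trait regime is the whole point, and
silently flooring probabilities would bias it; the only sentinel is −∞.

**Laplace step.**  The mode is found by derivative-free minimization of
the negative log posterior: Nelder–Mead and Powell both run from a
moment-estimate start (`π̂` = affected individuals / total individuals,
`δ̂` from the observed conditional proportions clipped to
admissibility), the better result is polished by a tight Nelder–Mead
pass.  Two searchers are used because each can stall on its own
pathological landscape (Nelder–Mead was observed converging to a
spurious near-boundary point on a zero-concordant-pair dataset that
Powell handles, and vice-versa protection costs little).  The
covariance is the inverse negative Hessian at the mode, by central
finite differences with relative step `1e−4` (shrunk ×10 up to six
times if a stencil point is inadmissible); failure to produce a
positive-definite matrix raises rather than degrading silently.  Data
with no affected individual and a flat prevalence prior are rejected
with advice to supply an informative prior (the mode diverges to
`π → 0`).

**MH step.**  Random-walk Metropolis–Hastings with a multivariate
normal proposal centered at the current point; proposal covariance =
Laplace covariance × `proposal_scale` (default 1.0, i.e. used as-is),
start = Laplace mode.  Constraint-violating proposals are counted as
ordinary rejections in the acceptance rate.  Default chain length for
reported analyses is 100,000 iterations; with the mode start, burn-in
defaults to 0 and no thinning is applied (both configurable).  One
integer seed drives the run: all proposal increments are drawn first,
then the acceptance uniforms, so runs are bit-reproducible per numpy
version.

**Summaries.**  Chains are back-transformed draw-by-draw to `π`, `δ`s,
`q`s and the contrasts; summaries are sample mean, SD (ddof = 1),
median (midpoint of central order statistics for even length), and the
HPD interval computed as the shortest window of `⌈mass·n⌉` consecutive
order statistics.  HPDs are computed on the natural scale — intervals
are not equivariant under the transforms, and natural scale is what a
reader of a concordance table needs.  `normal_approx_summary` samples a
normal cloud from the Laplace fit and pushes it through the same
back-transform, solely to show where the normal approximation fails
(skewed low-concordance posteriors).

## Synthetic data

The generator draws one multinomial vector of size `n` per zygosity
from the exact model cell probabilities, parametrized by
`(π, q^MZ, q^DZ, n_MZ, n_DZ, seed)`.  Reference scenarios mirror the
published simulation studies: independence (`π = 1%`,
`q^MZ = q^DZ = π`, 100,000 pairs per group) and familial clustering
(`π = 1%`, `q^MZ = 0.40`, `q^DZ = 0.10`, 4,000 MZ / 6,000 DZ pairs).
Because the generator *is* the model, recovery tests validate the
inference machinery, not the model's fit to real registries — they say
nothing about ascertainment bias, zygosity misclassification, age
structure, or prevalence differences between zygosities, none of which
are modeled.

## Verification

* Closed-form unit oracles: cell-probability algebra, transform
  round-trips (1e−10), likelihood vs an independent log-gamma
  multinomial pmf, Jacobian-only posterior at zero data.
* Grid-integration oracle: on small counts the posterior factorizes
  over `δ` given `π`, so posterior means are computable by 1-D/2-D
  quadrature; MCMC means agree within 3 Monte-Carlo standard errors
  (autocorrelation-adjusted).
* A prior-only chain (zero counts, flat priors) is tested against the
  grid-derived marginal of `π` by mean comparison and a
  Kolmogorov–Smirnov distance on thinned draws.
* HPD routine equals exhaustive shortest-window search for n ≤ 200.
* Calibration: across 200 replicate datasets at the familial-clustering
  scenario, fitted with 4,000-iteration chains to keep the whole suite
  fast, the 95% HPDs for `π`, `q^MZ`, `q^DZ` cover the truth in 90–99%
  of replicates.

## Numerical choices and limitations

* Optimizer tolerances: `fatol 1e−12`/`xatol 1e−10` on the polish pass.
* The acceptance rate with the unscaled Laplace proposal lands near
  0.45 on the reference datasets; `proposal_scale` is exposed should a
  target of ~0.23–0.44 be preferred for other data shapes.
* Counts with empty cells are handled by the convention `0·ln 0 = 0`;
  a positive count on a zero-probability cell gives −∞.
* Zero-total count vectors are accepted by the data type (they are the
  pooling identity) but rejected by the fitting entry points.
* Not covered: ascertainment correction, liability-threshold models,
  zygosity-specific prevalence, covariates, time-to-event censoring,
  dependent priors across the two δ parameters, and formal model
  comparison.
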