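# Methods

## Model and assumptions

`matefit` models mate formation as a two-stage process. Traits are sampled
independently per sex from homogeneous normal populations, X ~ N(μx, σx²)
for females and Y ~ N(μy, σy²) for males; an encounter between a female x
and a male y becomes a mated pair with probability γ·exp(−α(x−y−δ)²). The
model therefore assumes:

* a single continuous trait measurable in both sexes on a common scale;
* a matching rule — preference acts on the *difference* between own and
  partner trait, not on an absolute target value;
* a unimodal, symmetric (Gaussian) decay of mating probability around the
  optimal difference δ;
* free mixing: every individual can encounter every potential mate, with
  no depletion of the candidate pool;
* independence across pairs and across unpaired individuals.

Conditioning on mating gives a pair density whose normaliser is
E[e^{−α(X−Y−δ)²}], the MGF of a noncentral χ²₁ variable at
t = −α(σx²+σy²) with noncentrality λ = (μx−μy−δ)²/(σx²+σy²). Because
t ≤ 0 the MGF expression exp(λt/(1−2t))/√(1−2t) is always defined; it is
evaluated as λt/(1−2t) − ½log1p(−2t) in log space so that extreme α or
mean/SD mismatches cannot overflow or underflow. For the same reason only
the log pair density is exposed: at large α raw densities underflow double
precision.

Completing the square shows the conditional pair distribution is bivariate
normal with precision matrix [[1/σx²+2α, −2α], [−2α, 1/σy²+2α]]. This gives
three exact by-products used throughout: the within-pair correlation
ρ = 2α/√((1/σx²+2α)(1/σy²+2α)); closed-form conditional moments that serve
as an oracle for the rejection sampler; and fast density surfaces for
plotting. The correlation could equally be obtained by numerical
integration (a `method="quadrature"` cross-check mode is kept), but the
closed form is exact and is used as the primary path.

The likelihood multiplies the conditional pair density over mated pairs and
the marginal normal densities over unpaired females and males. γ cancels:
it is carried on `ModelParams` for simulation but never estimated. Either
singles set may be empty, at a cost: μx, μy and δ are not separately
identified without unpaired samples of both sexes, because an offset
preference is then indistinguishable from a shift in population means.
`fit_mle` refuses a free δ in that case; fixing δ (typically 0) restores
identifiability from pairs alone.

For discrete subpopulations believed to share one preference rule,
`multipop_log_likelihood` sums per-population likelihoods with common
(α, δ) and population-specific moments. Sharing exactly (α, δ) and freeing
all four moments per population is the default and only built-in scheme;
other sharing patterns can be profiled by hand through the `fixed` masks.

## Estimation

Optimisation uses L-BFGS-B over (α, δ, μx, μy, log σx, log σy); log-σ keeps
curvature comparable across coordinates. Bounds: α ≥ 1e−10, σ ≥ 1e−8.
Convergence tolerances are a relative log-likelihood change of 1e−9 and a
projected-gradient ∞-norm of 1e−6.

**Starting values** are moment-based: pooled per-sex sample means and ML
standard deviations; δ₀ = mean(x−y over pairs) − (x̄−ȳ over everyone); α₀
inverts the pair-correlation relation at the observed correlation, clipped
to [1e−4, 10]. Near α = 0 the surface is flat in δ (δ enters only through
α), so a single start can stall on the α boundary while an interior optimum
exists at a different offset; `fit_mle` therefore always runs a small
deterministic multi-start — the moment start plus two alternative strengths
corresponding to pair correlations of about 0.5 and 0.8 at the observed
variances — and keeps the best optimum. In null-data experiments this
removed essentially all of the optima a 12-point reference multi-start
could find beyond the single start. Three jittered restarts follow if no
run reports success. L-BFGS-B occasionally exits with an "ABNORMAL"
line-search status at a point that is already stationary (typically when
started at the exact optimum, as the null fit is); such results are
accepted as converged when the projected gradient is numerically zero.

**Standard errors** come from the inverse observed information, computed by
central finite differences on the internal scale (step max(1e−5, 1e−4·|θ|))
and delta-method transformed back to the natural scale. Evaluation points
are clipped at the parameter bounds, so curvature for an estimate sitting
on its bound (α̂ ≈ 0) is one-sided and the corresponding SE is only
indicative; a near-singular information matrix triggers a warning and a
pseudo-inverse. Wald intervals use the normal quantile (z = 1.959964 at
95%), not t.

**Auto-rescaling.** When the fitted α is below 1e−3 in input units (e.g.
millimetre-scale body sizes), α sits many orders of magnitude below the
other parameters and the surface is poorly conditioned — the raw-unit fit
can stall far from the optimum in the flat δ direction. The fit is then
repeated on 0.1×-scaled traits and back-transformed (α → α·c², δ → δ/c,
μ, σ → value/c, SEs correspondingly; log-likelihood corrected by the
change-of-variables Jacobian, one log c per observed trait value, so that
likelihood-ratio tests against unscaled fits remain valid). `--no-rescale`
disables this.

**Null model and LRT.** Under α = δ = 0 the likelihood factorises and the
MLEs are the pooled per-sex means and ML (1/n) standard deviations;
`fit_null` starts there and the closed form doubles as a unit-test oracle.
The random-mating test compares 2(llₑ − ll₀) to χ²₂. This matches the
convention used when such statistics are reported in the field, but note α
lies on the boundary of its parameter space under the null and δ is
unidentified at α = 0, so χ²₂ is mildly conservative: in the suite's
calibration study (1000 replicates, n_pairs = n_singles = 100) the
empirical type-I error at nominal 5% is ≈ 3.5–4%. No boundary-mixture
correction is applied.

## Simulator

`simulate_pairs` rejection-samples the mating process: independent
candidate draws from the per-sex trait distributions, accepted with the
mating probability, repeated until the requested number of pairs — fresh
candidates every attempt, no depletion, matching the independence
assumptions of the likelihood derivation. The long-run acceptance rate
equals γ times the pair normaliser, which the tests verify. Singles are
drawn independently of the pairing process (they model a random sample of
the population, not rejected candidates). A per-pair attempt budget
(default 1e5) guards against vanishing acceptance rates.

Defaults mirror the validation conditions used throughout the test suite:
μx = 10, μy = 12, σ = 2 for both sexes, γ = 1, n_pairs = n_singles = 100
with singles split exactly 50/50 by sex.

Two stress designs violate the model on purpose:

* **Skew** — traits drawn from a gamma distribution (default shape 2,
  scale 4). By default draws are shifted/scaled to the configured mean and
  SD so skewness (2/√k) is the only violation; raw-gamma mode keeps the
  natural scale.
* **Hidden structure** — three equal subpopulations with per-sex means at
  μ−ε, μ, μ+ε, mating confined within subpopulations, everything pooled
  unlabelled. ε = 0 degenerates to the homogeneous process.

What the simulator does *not* emulate: spatially explicit encounters, mate
search costs, finite mating seasons, within-pair measurement error, or
depletion of the singles pool as pairs form. Passing recovery tests
therefore show the estimator works when its assumptions hold (and degrades
as documented under skew/structure), not that those assumptions hold in any
particular field system.

## Validation studies and problem sizes

The acceptance-level tests are seed-pinned simulations sized to run in a
few minutes total:

* **Recovery** — 200 replicates per condition at n_pairs = n_singles =
  100, true α ∈ {0.25, 0.5, 1}, δ = 1: the median α̂ is within 25% of
  truth (with the expected mild upward bias at small samples, since α is
  bounded below), median δ̂ within 0.15.
* **Offset misspecification** — truth δ = 2 but δ forced to 0: α̂ drops
  below the full-model estimate in essentially every replicate (sign test
  over 200 replicates).
* **Hidden structure** — ε ∈ {0, 1.5, 3} with 80 replicates each: mean α̂
  increases and mean δ̂ decreases monotonically in ε. The chosen ε values
  span weak to moderate divergence relative to σ = 2.
* **Type-I error** — 1000 replicates at α = δ = 0, nominal 5% LRT; the
  empirical rate is required to fall inside the exact-binomial 99% band
  around 5% (see the boundary caveat above — the observed rate sits near
  the lower edge).

Published point estimates from the two field systems the method has been
applied to (marine snails, shell length; European common frogs, SVL) enter
the suite only as desk-check inputs for the preference-interval and
difference-CI arithmetic; the underlying field measurement tables are
archived externally and are not bundled, so those fits are exercised on
synthetic data of matching magnitudes instead.

## Numerical conventions and edge cases

* σ estimates use the ML (1/n) divisor everywhere, matching the likelihood.
* A per-sex sample with zero variance, or a σ of exactly 0, is rejected
  rather than limit-handled: the model assumes continuous variation.
* `preference_interval` requires α > 0 and raises an explicit
  infinite-width error at α = 0; p defaults to 10 (percent).
* The LRT refuses unconverged component fits, and treats a statistic below
  −1e−6 as an optimisation failure rather than clamping silently.
* Ties in the multi-start are broken by the first-found best optimum;
  the jitter RNG is fixed, so fits are fully deterministic.

## Known limitations

Categorical traits, asymmetric or multimodal preference functions, and
preference/trait (absolute-target) rules are out of scope. The Wald SE for
α is unreliable when α̂ is at or near the boundary — use the profile
likelihood or the LRT there. The multi-population likelihood assumes the
subpopulation assignment of every observation is known; it does not infer
hidden structure.
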