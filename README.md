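# matefit

Maximum-likelihood estimation of the strength of trait-matching mate
preference from phenotypes observed in the wild.

## The problem

Many animals and plants mate assortatively: trait values of mates are
correlated. Field biologists usually quantify this with a Pearson
correlation between trait values within mated pairs, but a correlation is
not a preference parameter — the same preference strength produces very
different correlations depending on how variable the trait is in the
population, and a correlation says nothing about whether individuals prefer
partners *like* themselves or partners offset from themselves by some fixed
amount. `matefit` estimates the preference parameters directly, so they can
be plugged into theoretical models of sexual selection, assortative mating
and speciation.

## The model

A quantitative trait is measured in both sexes: females carry
X ~ N(μ<sub>x</sub>, σ<sub>x</sub>²), males Y ~ N(μ<sub>y</sub>, σ<sub>y</sub>²).
A random encounter between a female with trait x and a male with trait y
results in mating with probability

    P(mate | x, y) = γ · exp(−α (x − y − δ)²)

* **α ≥ 0** — strength of preference (units 1/trait²). α = 0 is random
  mating; large α means only well-matched pairs form.
* **δ** — the trait difference x − y that maximises the mating
  probability. δ = 0 is strict trait matching; δ ≠ 0 is "similarity-like"
  offset matching (e.g. males preferring females slightly larger than
  themselves).
* **γ ∈ (0, 1]** — the mating probability at the optimum; it absorbs every
  trait-independent factor and cancels from the likelihood, so it is never
  estimated from phenotypes.

Conditioning on a successful mating gives a pair density proportional to
f(x) f(y) e^(−α(x−y−δ)²). Its normalising constant is the moment-generating
function of a noncentral χ²₁ variable evaluated at t = −α(σ<sub>x</sub>² +
σ<sub>y</sub>²), with noncentrality λ = (μ<sub>x</sub> − μ<sub>y</sub> −
δ)²/(σ<sub>x</sub>² + σ<sub>y</sub>²):

    E[e^{−α(X−Y−δ)²}] = exp(λt/(1−2t)) / √(1−2t)

so the full likelihood of n<sub>p</sub> mated pairs plus unpaired females
(S<sub>x</sub>) and males (S<sub>y</sub>) is available in closed form and is
maximised numerically (L-BFGS-B with box constraints). Unpaired samples of
both sexes are required to identify δ separately from a difference in
population means; with pairs alone, fix δ = 0.

The library also provides:

* a **rejection-sampling simulator** of the mating process (including
  gamma-skewed traits and hidden three-subpopulation structure, for
  robustness studies),
* a **likelihood-ratio test** against random mating (α = δ = 0, χ²₂),
* **Wald and profile-likelihood intervals**, and Wald intervals for
  parameter differences between two populations,
* the **p% preference interval** δ ± √(−log(1 − p/100)/α), the range of
  trait differences mating within p% of the maximum probability,
* the **correlation implied by the model**,
  ρ = 2α/√((1/σ<sub>x</sub>² + 2α)(1/σ<sub>y</sub>² + 2α)), which shows why
  a sample correlation alone cannot measure preference strength.

## Worked example

```python
import matefit as mf

cfg = mf.SimulationConfig(params=mf.ModelParams(0.5, 1.0, 10, 12, 2, 2),
                          n_pairs=200, n_singles=200, seed=7)
data = mf.simulate_dataset(cfg)

fit = mf.fit_mle(data)
print(fit.summary())

lrt = mf.lrt_random_mating(data, fit_full=fit)
print(f"LRT chi2({lrt.df}) = {lrt.statistic:.2f}, p = {lrt.p_value:.3g}")

pi = mf.preference_interval(fit.estimate("alpha"), fit.estimate("delta"), p=10)
print(f"10% preference interval: ({pi.lower:.2f}, {pi.upper:.2f})")
```

prints

```
log-likelihood -1051.93  (n_pairs=200, n_singles_x=100, n_singles_y=100, converged=True)
  alpha    0.4788 ± 0.1064 (95% Wald)
  delta    0.9209 ± 0.1894 (95% Wald)
  mu_x     10.04 ± 0.3484 (95% Wald)
  mu_y     11.98 ± 0.3394 (95% Wald)
  sigma_x  2.023 ± 0.2059 (95% Wald)
  sigma_y  1.983 ± 0.1997 (95% Wald)
LRT chi2(2) = 293.74, p = 1.64e-64
10% preference interval: (0.45, 1.39)
```

The simulating values (α = 0.5, δ = 1, μ<sub>x</sub> = 10,
μ<sub>y</sub> = 12, σ = 2) all sit inside their 95% intervals; random
mating is overwhelmingly rejected; and mating probability stays within 10%
of its maximum for pairs whose female is between 0.45 and 1.39 trait units
larger than her mate.

The same analyses are available from a shell:

```sh
matefit simulate --seed 7 --n-pairs 200 --n-singles 200 \
    --out-pairs pairs.csv --out-singles singles.csv
matefit fit --pairs pairs.csv --singles singles.csv --out result.json
matefit lrt --pairs pairs.csv --singles singles.csv --out result.json
matefit interval --alpha 0.16 --delta 1.39 --p 10   # -> (0.5785, 2.201)
matefit compare a.json b.json --param alpha
matefit recover --alpha 0.5 --reps 100 --out bias.tsv
```

Input tables are plain CSV/TSV with a header; `--column-map
female=FSize,male=MSize,sex=Sex,trait=SVL` adapts arbitrary column names.

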