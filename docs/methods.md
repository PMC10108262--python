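# Methods

## The problem

Common-garden experiments compare thermal performance curves (TPCs) of
somatic growth among populations to infer how they adapted to their local
temperature regime. Two patterns are usually distinguished: *adaptation to
seasonality* — parallel TPCs differing in elevation, with cold-origin
populations growing faster at every temperature (countergradient
variation) — and *adaptation to temperature* — TPCs that cross, each
population doing best near its home temperatures. `tpcgrowth` implements
the complete chain needed to make that inference honestly for a clonal
organism such as *Daphnia magna*: simulate growth data with the
experiment's hierarchical structure, fit per-population TPCs with
mixed-effects models, and translate somatic-growth TPCs into
population-growth (fitness-proxy) TPCs, where the scale of the growth
measure and any ecological mortality cost can qualitatively change the
verdict.

## Growth measures

Dry mass is estimated from gut length by the power-law allometry
`DM = 0.00679 * GL^2.75` (mg, mm), a relationship established for the
northern study population and applied to all populations. Two growth
rates are computed between the neonate and maturity measurements:
absolute `G = (M_mature - M_neonate)/age` (reported in ug/d) and
proportional `g = ln(M_mature/M_neonate)/age` (1/d). The two scales are
deterministically linked: with a standardized initial mass,
`g = ln(1 + G*t/M_init)/t`, a concave increasing map. The package also
provides the power-law shortcut `g = G^tau` (`0 < tau < 1`), the analytic
device used for derivative arguments; it is dimensionally informal and is
only applied where G is treated as a plain number. The exact log link is
the default for numeric work.

## The statistical model

Growth rate is modelled as a Gaussian linear mixed model:
population-specific quadratic polynomials in temperature centered at
12 °C (so each intercept is the growth rate at 12 °C, the coldest
treatment), a clone random intercept, and a clone random slope on the
linear centered-temperature term. Clones are the unit of biological
replication; their intercept–slope correlation is estimated by default
(the `lmer`-style free 2×2 covariance) with an option to constrain it to
zero. Fitting uses statsmodels `MixedLM`.

Candidate fixed-effect structures are all subsets of {population, T, T²,
population×T, population×T²} that respect marginality (T² needs T, an
interaction needs its main effects, population×T² additionally needs
population×T) — nine candidates from intercept-only to full. Candidates
are compared with AICc, `AICc = −2·loglik + 2k + 2k(k+1)/(n−k−1)`, where
`k` counts fixed coefficients plus variance/covariance parameters (two
variances and the covariance when estimated) plus the residual variance,
and `n` is the number of observations. Comparison uses ML; the selected
structure is refit by REML for reporting. Per-population coefficients are
reported as direct estimates, not contrasts: with a population effect in
the model the design matrix carries one indicator column per population,
a reparameterisation that leaves the likelihood (hence AICc) unchanged.

Numerical choices: optimisation tries lbfgs, then cg, powell and bfgs
until one converges; non-convergent fits are flagged and excluded from
"best" but retained in the comparison table. A random-effect covariance
with a near-zero eigenvalue is flagged singular. Data whose residuals are
numerically zero (e.g. simulated with all noise SDs zero) make the
Gaussian likelihood unbounded; such fits short-circuit to ordinary least
squares — exact for data lying on the fixed-effect surface — with
NaN likelihood and a `degenerate` flag. Records of animals that died
before maturity carry no growth measurement and are excluded before
fitting.

## Translation to population growth

For *Daphnia*, population growth rate scales linearly with proportional
somatic growth; the package's default conversion is the laboratory
relationship `r = 0.967 g − 0.089` (1/d), with the identity map available
for bare algebraic work. For a linear proportional TPC `g = α + βT`,
`dr/dT = βδ` is independent of α: parallel proportional TPCs stay
parallel, so countergradient variation on this scale remains
countergradient in fitness. For a linear *absolute* TPC the concave G→g
conversion makes `dr/dT = βτδ(α + βT)^(τ−1)` decrease with elevation α:
divergence in G can coexist with convergence in r. A per-population,
temperature-independent ecological mortality cost `m` (extra wild
mortality of fast growers, absent in lab assays) shifts a curve down;
`critical_mortality` computes the smallest m that makes two curves touch
(the minimum gap over the interval), and `find_crossings` locates
crossings by dense-grid bracketing (default 1000 points) plus Brent
root-polishing to 1e−8 °C; touches within 1e−10 without a sign change are
reported as tangencies, not crossings. `classify_adaptation` labels any
pairwise crossing inside the interval as consistent with adaptation to
temperature, and no crossing as countergradient / adaptation to
seasonality; the label is invariant to relabeling populations and to
common constant shifts. Quadratic fitted TPCs are translated by applying
the conversion pointwise and evaluated numerically; closed-form slopes
are reported only for the linear forms.

`figure_scenario()` packages the canonical two-population illustration:
absolute TPCs `G = α + 0.1T` with α = 1 vs 2, `M_init = 1`, `t = 1`,
δ = 1, and a mortality cost 0.3 paid only by the faster population. The
absolute gap is constant, the proportional gap shrinks with warming, and
the population-growth curves cross at T ≈ 8.583 °C.

## Synthetic data

The default `StudyDesign` is the experiment's layout: populations Norway,
Belgium, Spain; 10 clones each; temperatures 12, 15, 17, 19, 22, 24,
26 °C; 8 replicates per clone per temperature (1680 animals). Generating
fixed effects default to the study's REML estimates on each scale. The
clone SDs default to the reported values (0.0019 and 0.0023 on the
proportional scale; 0.072 and 0.055 ug/d on the absolute scale). Two
quantities are not reported and their defaults are stand-ins, not
inferences about the real data: the residual SD (0.02 1/d proportional,
0.5 ug/d absolute, chosen so simulated fixed-effect standard errors are
of the reported order) and the clone intercept–slope correlation (0).
All are configurable.

Rate-level simulation draws clone deviations once per clone and adds
i.i.d. Gaussian residuals per individual. Record-level simulation fixes
the neonate gut length at 0.4 mm, draws age at maturity from a lognormal
around a linearly decreasing mean (25 d at 12 °C to 8 d at 26 °C, CV
10%) — an invented development model that produces plausible fixtures,
not an estimate — and back-transforms the implied mature mass to gut
length through the allometry, so recomputing g from a record recovers
the latent rate to numerical precision. Optional dropout is
missing-completely-at-random and off by default.

What passing tests show, and do not show: the simulator generates data
from exactly the model the fitter assumes, so parameter-recovery results
demonstrate correctness of the estimation machinery (no bias, honest
SEs), not robustness to real-data features such as non-Gaussian
residuals, temperature-dependent variance, unbalanced mortality, or
allometry error.

## Parameter recovery and problem sizes

`recovery.recover_fixed_effects` simulates the full 1680-animal design,
fits the full model by REML, and averages estimates over seeds spawned
deterministically from a master seed. The packaged studies use 20 seeds
per scale — enough for Monte-Carlo standard errors an order of magnitude
below the estimated quantities — and the model-selection study uses 20
seeds per scenario with all nine candidates fitted by ML per seed.

## Known limitations

- One allometry for all populations; no population-specific mass
  calibration, no length-based growth, no mass loss.
- Mortality costs are temperature-independent constants; δ, τ and m are
  user parameters, never estimated from data.
- τ's numeric value is scenario-specific and dimensionally informal; the
  exact log link is the consistent alternative and the default.
- AICc parameter counting conventions differ across software; the
  convention above is applied consistently but absolute AICc values are
  not comparable across packages.
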