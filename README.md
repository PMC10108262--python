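# tpcgrowth

Thermal performance curves (TPCs) of somatic growth: simulation,
mixed-effects fitting, and translation into population growth rate.

When populations from different climates are reared in a common garden
across temperatures, cold-origin populations often grow faster at *every*
temperature (countergradient variation). Whether that pattern reflects
*adaptation to seasonality* (uniformly higher growth where seasons are
short) or *adaptation to temperature* (TPCs that cross, each population
best near home temperatures) cannot be read off the somatic-growth curves
alone: it depends on the scale of the growth measure and on mortality
costs of fast growth in the wild. `tpcgrowth` implements that full
inference chain for clonal organisms such as *Daphnia magna*, for
ecologists and evolutionary biologists running or reanalysing such
experiments.

## What it computes

- **Growth measures** — dry mass from gut length via the allometry
  `DM = 0.00679 GL^2.75` (mg, mm); absolute growth
  `G = (M_final − M_init)/t` (ug/d) and proportional growth
  `g = ln(M_final/M_init)/t` (1/d); the exact concave link
  `g = ln(1 + G·t/M_init)/t` and the power-law device `g = G^τ`, `τ < 1`.
- **TPC fitting** — per-population quadratics in temperature centered at
  12 °C, clone random intercepts and linear-temperature slopes
  (statsmodels `MixedLM`); all nine marginality-respecting fixed-effect
  structures compared by AICc under ML, winner refit by REML;
  per-population direct estimates, not contrasts.
- **Fitness translation** — population growth `r = δg + const − m` under
  the *Daphnia* conversion `r = 0.967 g − 0.089`, with per-population
  ecological mortality costs `m`; crossing detection, critical mortality,
  and classification as "crossing / adaptation to temperature" vs
  "no crossing / countergradient, adaptation to seasonality".
- **Synthetic data** — seeded hierarchical simulation of the
  3 populations × 10 clones × 7 temperatures × 8 replicates design, at the
  growth-rate level and at the individual measurement-record level.

See `docs/methods.md` for the model, defaults and limitations.

## Worked example

```python
import numpy as np
import tpcgrowth as tg

design = tg.StudyDesign()                  # the default common-garden layout
model = tg.default_proportional_model()    # study estimates as generating truth
table = tg.generate_growth_table(design, model, seed=42)

comparison = tg.select_best(table)         # ML + AICc, then REML refit
best = comparison.best_reml
print("best structure:", comparison.best_ml.structure.name)
a, se = best.fixed_estimates["intercept_Norway"]
print(f"Norway growth at 12 C: {a:.4f} +/- {se:.4f} /d")

effects = best.to_fixed_effects()
curves = {
    pop: (lambda T, p=pop: tg.DEFAULT_CONVERSION(effects.predict(p, np.asarray(T, float))))
    for pop in effects.populations
}
print(tg.classify_adaptation(curves, (12.0, 26.0)).label)

sc = tg.figure_scenario()                  # two-population worked scenario
res = tg.find_crossings(sc["slow"]["r"], sc["fast"]["r"], (0.0, 20.0))
print(f"scenario crossing at T = {res.crossings[0]:.3f} C")
```

prints

```
best structure: 1 + pop + T + T2 + pop:T + pop:T2
Norway growth at 12 C: 0.1680 +/- 0.0022 /d
no crossing: countergradient, consistent with adaptation to seasonality
scenario crossing at T = 8.583 C
```

The selected structure keeps both population-by-temperature interactions:
the three populations differ in intercept, slope and curvature. The
Norway intercept estimate (0.1680 ± 0.0022 /d) recovers the generating
value 0.1674 /d. Translated to population growth with no mortality cost,
the Norway curve stays above the southern ones across 12–26 °C — the
countergradient pattern — while the synthetic two-population scenario
shows how a mortality cost of 0.3 /d on the faster population makes
fitness curves cross at 8.583 °C even though its somatic advantage is
constant.

A command-line pipeline wraps the same steps:

```sh
tpcgrowth run --seed 42 --out-dir out/     # simulate -> rates -> fit -> translate
tpcgrowth simulate --seed 1 --out-dir data/
tpcgrowth compute-rates data/records.csv --out data/rates.csv
tpcgrowth fit data/rates.csv --out fit.json
tpcgrowth translate fit.json --mortality Norway=0.05 --out r.json
```

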