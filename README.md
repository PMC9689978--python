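# maltopt

Response-surface modelling and multi-response optimization of cereal
malting conditions.

## The problem

Malting quality is a compromise. Longer, warmer, wetter germination
solubilizes more of the grain (higher Congress-wort **extract**, the malt
yield) and lowers wort **viscosity** (better lautering), but it also drives
proteolysis too far (high **Kolbach index**, bad for foam and flavour
stability) and can depress the **apparent attenuation limit** (AAL, the
fermentability ceiling). A maltster tuning germination time, germination
temperature and degree of steeping therefore faces five responses pulling
in different directions.

`maltopt` implements the standard statistical route through this problem
for a three-factor micro-malting experiment, and ships the complete rye
(*Secale cereale*) landrace study it was built around: an 18-run
face-centred central composite design (FCCD, α = 1) in germination time
(4–6 d), temperature (12–18 °C) and degree of steeping (40–46 g/100 g),
with four centre replicates and one failed run handled by complete-case
analysis.

## The method

1. **Factor coding.** Each factor is scaled to x = (A − centre)/half-range
   ∈ [−1, 1], so e.g. x_time = (A − 5)/1 and x_temp = (B − 15)/3.
2. **Quadratic response surfaces.** Each response is fit by OLS to
   y = β₀ + Σβᵢxᵢ + Σβᵢⱼxᵢxⱼ + Σβᵢᵢxᵢ² over a selectable term subset;
   term sets are compared by AIC/BIC (full Gaussian likelihood, k = p + 1)
   and adjusted R².
3. **Adequacy.** The residual sum of squares is split into pure error
   (replicated design points, grouped in the reduced space of the factors
   the model actually uses) and lack of fit, giving the lack-of-fit F test;
   externally studentized residuals flag outliers.
4. **Desirability.** Each prediction is mapped to d ∈ [0, 1] by
   Derringer–Suich one-sided transforms (larger-is-better for extract and
   AAL, smaller-is-better for Kolbach index and both viscosities, bounds at
   the observed extrema, exponent s = 1), and aggregated as the geometric
   mean D = (Πdᵢ)^(1/5). D is maximized over the design box both by
   exhaustive grid search and by a real-valued genetic algorithm
   (linear-scaled roulette selection, local arithmetic crossover, random
   uniform mutation, 5 % elitism; population 100 × 100 generations).

## Worked example

```python
import maltopt as m

table = m.builtin_study()                    # 18 runs, run 10 missing
res = m.fit_ols(table, "extract", m.PUBLISHED_TERM_SETS["extract"])
print(res.summary())
print(res.anova())

specs = m.specs_from_table(table)            # bounds = observed extrema
best, _ = m.grid_search(m.PUBLISHED_MODELS, specs, table.design.factors)
```

The extract fit reproduces the study's model (coefficients in coded
units):

```
Response surface fit: extract
  n_obs = 17, terms = 6, df_resid = 11
  R2 = 0.9564, adj R2 = 0.9366, AIC = 10.75, BIC = 16.58

           estimate  std_error   t_value  p_value  significant
1           83.3652     0.1066  781.7735   0.0000         True
time         0.5636     0.0934    6.0314   0.0001         True
temp         0.8800     0.0864   10.1800   0.0000         True
time:temp   -0.7000     0.0966   -7.2428   0.0000         True
time^2      -0.5929     0.1774   -3.3422   0.0066         True
temp^2      -0.4109     0.1802   -2.2795   0.0436         True

ANOVA: extract
             df   sum_sq  mean_sq        F       p signif
model         5  18.0486   3.6097  48.3066  0.0000    ***
residuals    11   0.8220   0.0747      NaN     NaN
lack_of_fit   2   0.0170   0.0085   0.0949  0.9104     ns
pure_error    9   0.8050   0.0894      NaN     NaN
```

Germination time and temperature (and their interaction and curvatures)
drive extract; steeping degree drops out of the model. The lack-of-fit F
of 0.095 (p = 0.91) against a pure-error mean square from 9 replicate df
says the quadratic surface is adequate for prediction.

Optimization of all five responses then gives

```
grid optimum: D = 0.568 at 6 d, 12 °C, 44 g/100 g
GA optimum:   D = 0.5699 at 6.0 d, 12.6 °C, 43.0 g/100 g
```

i.e. both optimizers agree on the cool-and-long malting schedule: six days
of germination at 12–12.6 °C and ~43–44 g/100 g steeping, predicting
extract ≈ 82.7 % d.m. with the Kolbach index held near 55.6 %. A second
feasible region (short and warm: ≤4.5 d at ≥17 °C) also clears D ≥ 0.5 and
is exposed via `grid_search(..., report_threshold=0.5)`.

The same workflow is scriptable from the shell:

```
maltopt run-all --source builtin --seed 0 --outdir out/
maltopt fit extract
maltopt optimize-ga --seed 0
```

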