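# Methods

## Experimental design and coding

A face-centred central composite design (FCCD) in k factors consists of
the 2^k cube corners, 2k axial points on the cube faces (α = 1) and
n_center replicated centre points; every coded level is one of
{−1, 0, +1}. Factors are coded x = (natural − centre)/half-range with the
centre and half-range always derived from the stated [low, high] interval,
so low ↔ −1 and high ↔ +1 exactly. `fccd()` emits rows in a canonical
order (corners with the last factor fastest, axials per factor −/+, then
centres); a run-order permutation or RNG can be supplied, since randomized
execution order matters for the experiment but not for the analysis. The
bundled study design is stored in its executed (randomized) order.

## The built-in study

The package ships an 18-run FCCD on germination time (4–6 d), germination
temperature (12–18 °C) and degree of steeping (40–46 g/100 g) with five
measured malt-quality responses (Congress extract % d.m., Kolbach index %,
apparent attenuation limit %, Congress-wort and 65 °C isothermal-wort
viscosity mPa·s). One run (6 d, 15 °C, 43 g/100 g) failed for technical
reasons; it is kept in the table as all-missing and every analysis is
complete-case (n = 17). No imputation is implemented: the study's own
sensitivity check found imputed and complete-case results comparable, so
the simpler, assumption-light route is the default and only route.
Responses measured in duplicate enter as their reported means; the
duplicate level below the run mean is not modelled.

## Quadratic response surfaces

Each response mean is a second-order polynomial in the coded factors over
a term subset that always includes the intercept; terms are ordered
(intercept, linear, interaction, quadratic) for reproducible reporting.
Fitting is OLS (delegated to `statsmodels.OLS`), with classical
Gaussian-error standard errors and two-sided t p-values. Degenerate
inputs raise explicit errors: fewer complete cases than p + 1, or a
rank-deficient model matrix (e.g. all-centre data with quadratic terms).

**Fit indices.** AIC = −2ℓ + 2(p + 1) and BIC = −2ℓ + log(n)(p + 1) with ℓ
the full Gaussian log-likelihood and the +1 counting the residual
variance. This is R's `AIC()` convention; `statsmodels` omits the variance
from k, shifting both indices by a constant (2 and log n) that cancels in
any within-data comparison. The constant is documented here because only
candidate *ordering* is meaningful across conventions. Adjusted
R² = 1 − (1 − R²)(n − 1)/(n − p).

**Model selection.** Candidates are the full quadratic, the full set minus
each whole factor block, and the full set minus each single interaction or
square. Ranking is lexicographic (AIC, then BIC, then adjusted R²); when
AIC and BIC disagree, AIC wins and the full comparison table is part of
the report. A `force=` override retains a named term set regardless of the
indices — used for the attenuation limit, which is kept at the full
quadratic on substantive grounds (only its time×temperature interaction is
individually significant, but the full surface is needed to represent its
saddle shape).

**Published coefficients.** The five study equations are packaged as
`PUBLISHED_MODELS` constants so that prediction-based checks do not depend
on refit rounding; refitting the same term sets on the built-in table
reproduces every printed coefficient to within 2×10⁻⁴ in coded units.

## Lack of fit and diagnostics

Pure error is the within-group sum of squares over replicate groups, where
runs are grouped by **exact equality of the coded levels of the factors
appearing in the fitted term set** — factors the model ignores are
projected out. This reduced-space convention is deliberate: for the
extract model (no steeping terms) it pools the two steeping axials with
the four centres (a 6-replicate group) and pairs the corners, giving 9
pure-error df, while full three-factor models retain only the 4 centre
replicates (3 df). Exact equality needs no tolerance because FCCD coded
levels are exact by construction. If no group is replicated, the
lack-of-fit rows are omitted with a warning rather than an error.

The ANOVA table reports model (corrected total − residual), residual,
lack-of-fit and pure-error rows, each with mean square = SS/df,
F(model) = MS_model/MS_residual, F(lof) = MS_lof/MS_pe, p-values from the
F distribution, and significance bands ***/**/* at 0.001/0.01/0.05 with
"ns" above 0.05. The lack-of-fit label is whatever the computed p-value
implies; borderline cases (the Congress-viscosity model's F = 6.17 on
(5, 3) df sits near the 0.05 boundary) are reported, not forced.

Outlier screening uses externally studentized residuals (leave-one-out
variance, via `statsmodels` influence measures); exactly interpolated
points (leverage 1) and fits with fewer than 2 residual df raise errors.

## Synthetic data generator

`simulate_responses` draws y = (polynomial mean at the coded design point)
+ N(0, σ²), iid across runs and independent across responses — exactly the
error structure the OLS/ANOVA machinery assumes, which is the point: it
makes estimator unbiasedness, CI coverage, type-I error rates and
noise-free exact recovery testable without any external data. Per-response
streams are spawned from one master seed (`numpy` `SeedSequence`), so
tables are bit-reproducible and adding a response never perturbs the
others. `mask_runs` blanks whole runs to emulate failed experiments.
`study_generator` bundles the study conditions: the 18-run design with the
published surfaces as truth and σ = 0.3 by default, the order of the
extract model's residual SD (√0.0747 ≈ 0.27 % d.m.). What the generator
does **not** emulate: correlated multi-response errors,
run-order/batch effects, heteroscedasticity, and the duplicate-measurement
layer — so passing recovery tests certify the statistical machinery, not
robustness to those real-data features.

## Desirability optimization

One-sided Derringer–Suich transforms with bounds (L, U) and exponent
s = 1: larger-is-better d = clip((y−L)/(U−L), 0, 1)^s, smaller-is-better
its mirror. Bounds default to the observed extrema of the run table
(overridable); predictions outside [L, U] clamp d to 0 or 1 rather than
erroring, since quadratic surfaces extrapolate modestly beyond the
observed range even inside the design box. Overall D is the geometric
mean, computed in log space with an explicit zero short-circuit.

The default search grid uses natural-unit steps of 1 per factor
(1 d × 1 °C × 1 g/100 g, 147 points). This is the resolution at which the
study grid was evaluated and is the only one consistent with its reported
maximum D = 0.568 at integer levels — a finer temperature grid surfaces
D ≈ 0.570 near 12.5 °C and moves the argmax. Steps are configurable; ties
break to the lexicographically first natural point (grids are emitted in
lexicographic order and argmax takes the first maximum). `grid_search` can
return all points above a D threshold, which exposes both feasible regions
(long-cool and short-warm) rather than only the winner.

## Genetic algorithm

A from-scratch real-valued GA over the coded box, defaults matching the
study settings: population 100, 100 generations, crossover probability
0.8, mutation probability 0.1, elitism 5 % (= 5 individuals).

* **Selection** is roulette sampling after linear fitness scaling. The
  default `"goldberg"` mode preserves the scaled mean and caps the scaled
  maximum at P × mean (pressure P = 2), anchoring the minimum at zero when
  the cap would go negative and clipping by absolute value — the classic
  scheme used by the reference real-coded operator suite. A `"bounded"`
  mode instead shifts fitness by (f_max − f_min)/(P − 1), capping the
  best-to-worst selection ratio at exactly P (e.g. fitness (1, 0) →
  probabilities (2/3, 1/3)). The Goldberg mode is the default because its
  stronger late-stage exploitation is needed to reliably reach the
  boundary optimum; selection internals are otherwise exchangeable.
* **Crossover**: local arithmetic — per-gene convex combinations with
  independent U(0, 1) weights, so children stay inside the box and
  genewise sums are conserved.
* **Mutation**: with probability 0.1 per chromosome, one uniformly chosen
  gene is redrawn uniformly in its bounds. The study states the rate per
  parent chromosome, matching the cited operator; a per-gene mode exists
  behind `per_gene_mutation` for users who want the other convention.
* **Elitism**: each generation's top 5 replace the worst-evaluated
  offspring of the next, so best-so-far fitness is provably non-decreasing.

Fitness functions are evaluated vectorized on the whole population; a full
run costs ~10⁴ surface evaluations and ~0.1 s. Non-finite fitness aborts
with the offending chromosome named.

## Numerical and reporting choices

* Report rounding follows the study: extract/KI/AAL to 1 dp, viscosities
  to 2 dp, D to 3–4 dp; full-precision values are always written
  alongside. Reproduction checks accept half-unit-in-the-last-digit ties,
  several of which occur because the study predicted from unrounded
  coefficients (e.g. its 5.27 mPa·s at the grid optimum vs 5.283 from the
  printed equation).
* The ANOVA "model mean square" is SS/df. (The study's printed table
  divides the model SS by 3 in that one column; its F statistics are
  nonetheless consistent with SS/df, which is what we report.)
* Pipeline runs are deterministic given the config seed; each stage logs a
  structured line with the input hash and seed.

## Problem sizes used in the test suite

Monte-Carlo checks run at sizes chosen to make their statistical bands
sharp but cheap: 200 seeds for coefficient recovery/CI coverage (MC SE of
coverage ≈ 0.015 against a ±0.03 band) and per-term type-I rates, 20 seeds
for the GA fitness-band check, and a 0.01-coded-step exhaustive search
(~8 × 10⁶ points, evaluated in chunks) as the continuous-optimum oracle.

## Known limitations

Only one-sided desirability transforms (no target-is-best) and a single
shared exponent s; no per-response importance weights. No rotatable or
spherical CCDs, Box–Behnken or fractional designs. No regularized or
robust regression, no canonical/ridge analysis of stationary points, and
predictions are always made in coded space and decoded afterwards —
natural-unit regression equations are not produced. Viscosity responses
are modelled on the raw scale as in the study, although a log link might
suit them; transformation search is out of scope.
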