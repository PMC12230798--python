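# Methods

## Model

The demographic model couples a discrete seed-bank class to a continuous
size-structured plant population. Size is log-transformed plant height
(log cm), measured in the first July of a plant's life; the projection
interval is roughly one year (first-July census to the following late-spring
census). Dynamics:

    S(t+1)   = s_sb (1 − e) S(t) + ∫_L^U p(x) f1(x) seed (1 − e) n(x,t) dx
    n(y,t+1) = e_sb f_d(y) S(t) + ∫_L^U [ s(x) g(y,x) + p(x) f1(x) seed · e f_d(y) ] n(x,t) dx

Seeds produced by a size-x plant (`p(x) f1(x) seed`) either establish directly
within the interval (probability e) as recruits with size density f_d, or
enter the seed bank (probability 1 − e), from which they later emerge with
probability e_sb per year after surviving with probability s_sb. The model is
deterministic, density-independent and spatially unstructured; λ is the
dominant eigenvalue of the discretized kernel.

Assumptions worth making explicit:

- All vital rates depend on size linearly (on the logit scale for the binary
  rates). This mirrors the source analysis, which restricted itself to linear
  size relationships because of the small dataset.
- Reproduction is pollen-limited in the greenhouse, so seed output is spliced
  together from greenhouse flowering-shoot counts and field-measured pods per
  inflorescence × seeds per pod, averaged plant → population → region
  (constants 79 and 42 seeds per flowering shoot for the invasive and native
  region respectively).
- e, e_sb and s_sb come from prior field studies of invasive populations and
  are held constant across origins and treatments; they are never resampled by
  the bootstrap.
- The flowering-shoot function f1(x) = 2.67 − 0.49 x goes negative above
  x ≈ 5.4; the kernel clamps it at zero. The published table is silent on
  this; the clamp only matters if the size domain extends that far.
- The seed-input row of the matrix applies no additional first-winter
  survival to new seeds (the equations as published carry only the (1 − e)
  factor); f_d is not renormalized to [L, U] — any leakage is surfaced by the
  eviction diagnostic instead of silently corrected.

## Parameters

One `VitalRateParams` per origin × treatment cell. The shipped canonical table
(`lupine_ipm/data/table2.yaml`) carries the published estimates; survival and
flowering-shoot coefficients were estimated from the pooled data (printed
sample sizes 220 and 46 for every cell) and are therefore identical across
cells.

| component | meaning | units / scale | canonical values |
|---|---|---|---|
| s(x) = logit⁻¹(a_s + b_s x) | survival over the interval | probability | pooled (1.13, 1.16) |
| g(y,x) = N(a_g + b_g x, σ²_g) | size at t+1 | log cm | per cell, e.g. invasive-intact (4.40, −0.16, 0.22) |
| p(x) = logit⁻¹(a_p + b_p x) | flowering probability | probability | per cell, e.g. invasive-intact (7.89, −3.09) |
| f1(x) = max(0, a_f1 + b_f1 x) | flowering shoots | count | pooled (2.67, −0.49) |
| f_d = N(μ_fd, σ²_fd) | recruit log size | log cm | per cell, e.g. invasive-intact (2.52, 0.19) |
| seed | seeds per flowering shoot | count | 79 (invasive), 42 (native) |
| e, e_sb | establishment (direct / from bank) | probability | 0.122 |
| s_sb | seed-bank survival per year | probability | 0.977 |

## Discretization and size limits

Midpoint rule: the matrix is `matrix_dim × matrix_dim` (default 50) with
index 0 the seed bank and 49 equal cells partitioning [L, U]; kernel densities
are evaluated at cell midpoints and multiplied by the cell width h. λ changes
by < 0.5% between mesh 50, 100 and 200 for the canonical parameters, and by
< 0.5% when the limits are widened by 20% of the span, so the default mesh is
adequate.

The source protocol sets L = 0.9 × the minimum and U = 1.1 × the maximum
observed size over the whole study; those extrema are not published. The
canonical fallback emulates them from the shipped distributions: first-year
sizes contribute μ_fd ± 4 SD per cell, second-year sizes contribute the
stationary point of each growth function (a_g / (1 − b_g), well-defined here
since every b_g < 1) ± 4 residual SD; the 0.9×/1.1× rule is then applied to
the pooled extremes. This covers > 99.99% of every recruit-size mass and
leaves every growth kernel eviction-free, and λ is insensitive to widening.
The 0.9/1.1 factors act on the log-size scale by default; a `raw` option
applies them to back-transformed heights (equivalent to adding ln 0.9 /
ln 1.1), since the original text does not say which scale was used. Eviction
is diagnosed per source cell (retained midpoint mass of g and f_d, flag below
1 − 0.01) and never corrected.

## Estimation

- Survival and flowering: logit-link binomial GLM by IRLS (relative tolerance
  1e−10, 100 iterations max). Degenerate outcomes (single class), diverging
  coefficients or perfectly separated fits raise a `SeparationError` naming
  the rate rather than returning silently absurd estimates.
- Growth: OLS of size_t1 on size_t among survivors; σ²_g is the unbiased
  (n − 2) residual variance.
- Flowering shoots: shoot counts are non-negative, and the data model
  (and the synthetic generator) treats them as Gaussian truncated at zero.
  The default estimator is therefore zero-truncated-Gaussian maximum
  likelihood (BFGS from the OLS solution, standard errors from the numerical
  Hessian), which recovers the latent linear mean without the downward bias
  plain least squares incurs when the truncation binds (the bias is ≈ 6 SE on
  the slope at n = 10,000 with the default residual SD of 1). `shoot_model="ols"`
  is available for comparison; the two coincide as truncation mass → 0.
- Recruit size: sample mean and (n − 1) variance of first-year size per cell.
- Seed constant: per plant, mean seeds per pod over its three sampled pods ×
  pods per inflorescence; averaged within population, then across populations.
- Random effects (population, block) are not fitted: the kernel consumes only
  fixed-effect coefficients, and the canonical table prints only those. The
  generator's random-intercept SD defaults to 0 accordingly.

## Synthetic data

`simulate_greenhouse` inverts the fitted-model family: per cell, first-year
size ~ N(μ_fd, σ²_fd); survival ~ Bernoulli(logit⁻¹(a_s + b_s x)); second-year
size ~ N(a_g + b_g x, σ²_g) for survivors; flowering ~ Bernoulli of the
logistic; shoot count ~ N(a_f1 + b_f1 x, 1.0) truncated at zero for flowerers.
Defaults match the study design: 55 individuals per cell (220 total), labels
assigned round-robin over 5 populations per origin, 5 blocks and 3 inoculum
source sites. The shoot residual variance 1.0 is a choice — the published
table prints none — and only affects the generator and the shoot fit, never
the kernel (which uses only the f1 mean). Field fecundity: pods per
inflorescence and seeds per pod are Poisson with means (18.0, 4.4) invasive
and (12.0, 3.5) native, whose products match the regional seed constants; the
distribution is a choice, as only the sampling design (15 plants × 5
populations, 3 pods per plant) is documented.

What the generator does not emulate: population/block heterogeneity (unless
the random-intercept knob is raised), overdispersed or integer shoot counts,
size-measurement error, and any treatment effect on survival or shoot number
(those rates are generated from the pooled coefficients, as fitted). Passing
tests therefore demonstrate internal consistency of the pipeline — parameter
recovery, eigenvalue correctness, bootstrap determinism — not robustness to
real-data violations of the fitted-model family.

At the study's sample sizes the design is information-poor in two places, and
the pipeline surfaces rather than hides this: ~98% survival leaves a handful
of deaths in 220 plants, and the sparsest cell has 2–8 flowerers, so logistic
refits on bootstrap resamples separate frequently. Degenerate replicates are
redrawn and counted; more than 20% redraws is an error.

## λ, bootstrap, sensitivity

λ: power iteration (L1-normalized, relative tolerance 1e−10, 10,000 iteration
cap, explicit non-convergence error) cross-checked against
`scipy.linalg.eigvals` at 1e−8 relative.

Bootstrap CI: individuals are resampled with replacement within each origin ×
treatment stratum, field plants within each population; all vital rates are
refitted, kernels rebuilt on the size limits resolved from the point-estimate
data, and λ recomputed; the CI is the central 95% percentile interval
(2.5/97.5), deterministic given the RNG seed. The constants e, e_sb, s_sb are
fixed, not resampled.

Sensitivity: each component (intercepts and slopes separately, the recruit
mean, and the four constants) is multiplied by 0.99 — sign-preserving, so a
negative slope is shrunk toward zero and a zero component yields sensitivity
exactly 0 — the kernel is rebuilt from scratch at fixed [L, U], and
|λ′ − λ| / λ is reported as an absolute value. The growth and recruit-size
variances are excluded by default (a flag adds σ²_g), matching the component
list of the source analysis. For all four canonical cells the flowering and
shoot components dominate and survival is negligible, the expected pattern for
a fast-growing population.

## Relation to the published growth rates

The source study prints a λ range of 1.83–4.21 and intact-vs-autoclaved
increases of 130% (invasive) and 30% (native); the printed endpoints and the
130% are mutually consistent (4.21/1.83 − 1 = 1.30), so the invasive cells are
both extremes. Building the kernels from the published equations and the
published estimates exactly as printed, this package obtains
λ = 8.61 / 2.84 (invasive intact / autoclaved) and 3.44 / 2.69 (native),
i.e. range 2.69–8.61 with +204% and +28%.

The native-origin comparison reproduces the printed +30% almost exactly, which
says the model structure implemented here matches the one used. The
invasive-origin values do not, and no defensible re-reading closes the gap:
the result is stable under mesh refinement and any eviction-free size domain;
alternative structural readings (no direct establishment, all seeds routed
through the bank, survival-weighted fecundity, probit links, SD-for-variance
readings, swapped regional seed constants, e = 0.0122) either barely move λ or
destroy the native-origin agreement. Both invasive cells would need their
fecundity scaled by ≈ 0.44 — equivalent to a seeds-per-shoot constant of ≈ 35
rather than the printed 79 — to hit the printed endpoints, while the native
cells need no change. The single number shared by exactly the two invasive
cells is that seed constant, so the most plausible explanation is that the
value used in the original computation differed from the printed one. The
package deliberately reports what the published inputs imply rather than
rescaling anything toward the printed outputs.

## Numerical choices and edge cases

- Midpoint-rule entries differ from exact per-cell integrals by up to ~2–3% on
  mass-carrying entries at mesh 50 (the textbook h³ K″/24 bound); λ built from
  exactly integrated Gaussian cell masses agrees with the midpoint λ to better
  than 0.1%, which is the accuracy that matters.
- Exactly collinear degenerate inputs: a two-point growth fit returns residual
  variance 0, which the kernel rejects (it needs σ²_g > 0).
- All-equal observed sizes still yield a valid domain (L = 0.9 s < 1.1 s = U
  for s > 0).
- A matrix with a non-real dominant eigenvalue pair makes the power iteration
  oscillate; it reports non-convergence with the iteration count instead of
  returning a wrong value.
- Kernel entries are validated finite and non-negative at build time, with the
  offending (i, j) named.

## Limitations

- Greenhouse demography without competition; the λ values are not field
  predictions.
- Establishment and seed-bank constants are borrowed from invasive-range field
  studies and shared across all four cells, which can only attenuate
  origin × treatment contrasts that act through establishment.
- The bootstrap treats the fitted model family as true and refits it; it does
  not propagate uncertainty in e, e_sb, s_sb or in the choice of size limits.
- Sensitivities are one-at-a-time 1% perturbations, not eigenvector-based
  analytic sensitivities; they quantify local response only.
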