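# Methods

## Morphometrics

Egg volume is *V* = β·*L*·*W*² with length and width in millimetres and a
species-specific constant β (0.509×10⁻³ shearwater, 0.476×10⁻³ gull)
yielding cm³. Aggregation is **clutch-first**: eggs are averaged within
each nest×year clutch and clutch means are then averaged within the year,
so a 3-egg gull clutch carries the same weight as a single-egg clutch.
Per-egg pooling is available (`clutch_first=False`) but off by default.
A width exceeding its length is treated as a warning rather than an error,
because real calliper datasets contain occasional transcription swaps; no
automatic swap is applied. The study window is configurable and defaults
to 2002–2019 (18 breeding seasons). A year inside the window with no
clutches for a species is an error, because the synchrony statistic
requires contiguous series.

## The synchrony statistic Φ

Each series of k annual values is mapped to k−2 interior states:
trough (1) if xₜ₋₁ > xₜ ≤ xₜ₊₁, increase (2) if xₜ₋₁ ≤ xₜ ≤ xₜ₊₁,
peak (3) if xₜ₋₁ ≤ xₜ > xₜ₊₁, decrease (4) if xₜ₋₁ > xₜ > xₜ₊₁.
The four conditions partition every real triplet, ties included; ties are
resolved by the inequalities themselves and no jitter is added.

The 4×4 transition matrix **T** is estimated from the transitions of
**both** state sequences pooled — the null hypothesis treats the two
series as independent chains *sharing* one transition structure — with a
row never observed as an origin set to the uniform row (¼,¼,¼,¼), which
neither forbids nor biases unobserved dynamics. A per-series option
exists.

At each interior year the occupancy vector **s**ₜ holds the proportion of
series in each state (with two series, entries in {0, ½, 1}) and the
entropy Hₜ = −Σ sⱼ ln sⱼ is 0 when the series agree and ln 2 otherwise.
The null distribution of H is simulated: chains are started from the
stationary distribution of **T** (power iteration from the uniform vector,
tolerance 10⁻¹⁰; for a non-ergodic **T** the uniform fixed point is
returned) and advanced independently; H̄ₙᵤₗₗ pools all replicates and time
steps, which stationarity justifies. Default 10,000 replicates. Then

  Φₜ = 1 − Hₜ/H̄ₙᵤₗₗ,

so Φₜ = 1 exactly when the series share a state, Φₜ ≈ 0 under
independence, and Φₜ < 0 for systematic disagreement.

**Significance.** A one-sided empirical p-value toward low entropy is
attached per year, with the add-one correction
p = (1 + #{H_null ≤ Hₜ})/(1 + N) so p is never zero; α defaults to 0.05.
This construction is the package's explicit choice — the statistic itself
does not prescribe a test.

**Degenerate nulls.** If the fitted **T** has an absorbing state (e.g. the
last observed state never transitions out), the stationary distribution
concentrates there and H̄ₙᵤₗₗ can be 0. Φ is then undefined and the run
raises a flagged error rather than returning a number; perfect synchrony
(Hₜ = 0, i.e. state agreement) remains well defined and the validation
simulations fall back to it in such replicates (well under 1% of
default-scenario draws).

## Breakpoint cross-correlation

Pearson correlation at lag 0 of the paired annual means, computed
separately for years strictly before the breakpoint and from the
breakpoint year onward (the closure year belongs to "after"; configurable).
Spearman is available. Each segment needs ≥ 3 paired years. No
significance bands are attached; the before/after pair is a descriptive
summary.

## Environmental-buffering GLM

One row per species×year (n = 36 at the default window). The response is
the annual mean volume, z-scored globally across both species by default —
this puts the two species (≈80 vs ≈34 cm³) on one scale so species,
synchrony and environment coefficients are comparable; a raw-scale option
exists. The synchrony covariate is the binary Φₜ = 1 indicator derived
from the synchrony stage (years outside the Φ axis are coded 0); year, when
included, enters continuous and centered.

Candidates are all hierarchical subsets of {Sp, Sync, W_NAO} with the
two-way interactions Sp:Sync, Sp:W_NAO, Sync:W_NAO (18 models), optionally
augmented with Year and Closure main effects. Fits are ordinary least
squares; the reported log-likelihood is the Gaussian likelihood maximized
over the coefficients *and* the variance, i.e. σ̂² = RSS/n, so that

  AICc = −2 logLik + 2k + 2k(k+1)/(n−k−1)

is internally consistent with k = (slope terms + intercept) + 1 for the
residual variance. Standard errors and Wald 95% CIs
(estimate ± 1.96·SE) use the conventional unbiased variance RSS/(n−p),
mirroring standard GLM software, where the likelihood is ML but inference
is not; pure-ML standard errors at n = 36 would shrink intervals by ~10%
and visibly undercover. Model averaging over the ΔAICc ≤ 4 set is **full**
(zero-substitution): a model lacking a term contributes 0, and the
unconditional variance Σ wᵢ(seᵢ² + (bᵢ − b̄)²) combines within-model
sampling variance with between-model spread. An effect is "significant"
when its CI excludes zero, boundaries counting as overlap.

`phase_slopes` fits the full Sp×W_NAO×Closure factorial and reports each
species' environmental slope in each phase plus the gull's between-phase
contrast. No "buffering percentage" is derived: such a summary depends on
an arbitrary denominator, so the contrast (with its SE and p) is the
reported quantity.

## Synthetic data generator

The generator encodes the subsidy-decoupling design: an AR(1) Gaussian
environmental index (defaults: mean 0, sd 1, autocorrelation 0 — the index
enters the analysis only as an exogenous regressor, so its marginal
distribution is what matters); species annual means
X = baseline + slope(regime)·env + ε; the gull buffered (slope 0, extra
noise sd 0.9 cm³) before the 2010 closure and coupled afterwards.
Defaults: baselines 80 (gull) and 34 cm³ (shearwater), coupled slope
−1.1 cm³ per index unit for both species, residual sd 0.2 cm³, 32 gull
clutches/yr of 3 eggs and 105 shearwater clutches/yr of 1 egg (the study's
approximate annual nest counts), widths ~N(49, 1) and N(36, 1) mm. The
effect sizes were set once so that the median replicate shows perfect
state agreement in about 7 post-closure years, the qualitative pattern the
analysis targets.

Egg records are generated **backwards through the volume formula**: a
clutch target volume is drawn around the annual mean (between-clutch sd
4.0 / 1.7 cm³), a width is drawn per egg, and the length is solved from
V = β·L·W², both rounded to 0.1 mm; draws with L ≤ W are retried. This
makes the morphometric stage testable to rounding error. All randomness
derives from one seed fanned out into named substreams (environment,
volumes, eggs), so each artifact is individually reproducible.

**What the generator does not emulate:** demographic structure, observer
error beyond rounding, within-clutch laying-order effects, temporal
autocorrelation in the residuals, and any nonlinearity in the
environment–volume link. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that real data satisfy
those assumptions.

## Validation simulations (problem sizes)

- **Null self-consistency:** T fitted from one scenario; 2,000 fresh
  independent chain pairs of length 16 vs a 10,000-replicate null; mean Φ
  should be ≈ 0 (observed ≈ −0.004).
- **Slope coverage:** 500 replicates of 36-row frames with environmental
  slope −0.4 (standardized scale, residual sd 0.5, species effect 1.5,
  synchrony effect −0.5), full 18-candidate selection and averaging;
  the averaged CI covers the truth in ≈ 95–96% of replicates.
- **Regime-shift detection:** 500 scenario replicates; cc_after >
  cc_before and a post-closure majority of Φ = 1 years co-occur in ≈ 95%.
- **Round trip:** generator → eggs CSV → annual series at 50 clutches/yr
  recovers the generating means within 2% (max over years and species).

These sizes keep the full suite and the acceptance script at a few seconds
each while leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- Φ with two series takes only two entropy values per year (0 or ln 2), so
  per-year p-values are coarse; the statistic is most informative as a
  timeline and through the perfect-synchrony indicator.
- The transition matrix is first-order and shared; longer memory or
  species-specific dynamics would bias H̄ₙᵤₗₗ.
- AICc model averaging with zero substitution shrinks weakly supported
  coefficients toward zero; coverage of the averaged CI is slightly below
  nominal for hard-to-detect effects.
- The pipeline assumes exactly two species with identical, contiguous year
  coverage.
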