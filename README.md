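# eggsync

Analysis pipeline for **interspecific synchrony in seabird breeding
investment**: do two sympatric species whose egg volumes track the same
environmental driver fluctuate in step — and does access to anthropogenic
food subsidies (landfill waste) mask that synchrony by buffering one
species from environmental variation?

The pipeline was built for a two-species system — a landfill-using gull
(3-egg clutches) and a strictly pelagic shearwater (single-egg clutches) —
observed over 2002–2019 with a landfill closure in 2010, but every stage is
generic over two contiguous annual series.

## What it computes

1. **Morphometrics.** Egg volume from calliper measurements,
   *V* = β·*L*·*W*² (mm in, cm³ out; β = 0.509×10⁻³ shearwater,
   0.476×10⁻³ gull), aggregated clutch-first into per-species annual mean
   series *X*ᵢ,ₜ.
2. **State-based Markov-chain synchrony (Φ).** Each series is classified
   into four states at every interior year — trough, increase, peak,
   decrease — by the inequalities between a value and its neighbours. With
   a shared 4×4 transition matrix **T** estimated from both state
   sequences, the occupancy entropy
   *H*ₜ = −Σⱼ *s*ⱼ(ₜ) ln *s*ⱼ(ₜ) is compared with its Monte-Carlo
   expectation under independent stationary chains:
   **Φₜ = 1 − Hₜ / H̄ₙᵤₗₗ**. Φₜ = 1 means both series occupy the same
   state (perfect synchrony); values near 0 are consistent with
   independence.
3. **Breakpoint cross-correlation.** Pearson correlation of the paired
   annual means before vs from the closure year onward.
4. **Environmental-buffering GLM.** Gaussian identity-link models of the
   standardized annual mean volume on species, a perfect-synchrony
   indicator (Φₜ = 1), and the winter NAO index, over all hierarchical
   candidates with two-way interactions; AICc selection
   (AICc = −2 logLik + 2k + 2k(k+1)/(n−k−1), k counting intercept and
   residual variance), Akaike weights, full model averaging over the
   ΔAICc ≤ 4 set, and per-species per-phase environmental slopes.
5. **Synthetic data generator.** The subsidy-decoupling scenario: both
   species share an AR(1) environmental index; the gull's environmental
   slope is zeroed (with extra idiosyncratic noise) before closure and
   matches the shearwater's afterwards. Egg-level fixtures are produced by
   drawing widths and solving the volume formula for length, so the whole
   chain is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on a seeded
synthetic scenario (fixtures go to `scratch/fixtures/`, outputs to
`results/`):

```
python analysis/01_simulate.py
python analysis/02_egg_volumes.py
python analysis/03_synchrony.py
python analysis/04_crosscorrelation.py
python analysis/05_buffering_glm.py
python analysis/06_validation.py
```

With the default scenario (seed 20) this prints, among other things:

```
cc_before = -0.192 (n=8), cc_after = +0.863 (n=10)
coupling increased across the closure year
```

— the cross-correlation jump that signals decoupling giving way to shared
forcing — and

```
perfectly synchronized years (phi = 1): [2003, 2004, 2005, 2013, 2014, 2015, 2016, 2017, 2018]
```

the Φₜ = 1 years against a simulated null entropy of 0.50 nats. The GLM
stage reports the AICc model table and averaged coefficients; in this
realization the averaged environmental slope is −0.047 (CI excludes 0) and
the gull's slope steepens by −0.075 per index unit after closure
(p < 0.001), the buffering-loss signature the scenario encodes.

The same machinery is exposed as a CLI (`eggsync simulate`, `volumes`,
`sync`, `ccf`, `glm`, `run-all`) and as plain library functions
(`eggsync.run_synchrony`, `eggsync.model_selection`, ...).

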