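# Methods

## The assay and the estimator

A drop-freezing assay cools an array of `N0` droplets of volume `V` at a
constant rate and records each droplet's freezing temperature. The analysis
is *singular*: nucleation is treated as time-independent, every nucleus has a
characteristic freezing temperature, and a droplet freezes at the warmest
characteristic temperature it contains. The cooling rate is therefore carried
as metadata only.

Events are discretised onto a descending temperature grid (default step
0.2 °C, the resolution at which onsets and medians are conventionally
reported; configurable). A droplet observed frozen exactly at a grid
temperature counts as frozen at that temperature (closed-above convention),
so `N(T)`, the unfrozen count at grid point `T`, counts droplets freezing
strictly below `T`. Censored droplets — still liquid at the coldest
temperature reached — stay in `N(T)` at every grid point.

The cumulative IN concentration is `K(T) = ln(N0/N(T))/V` (IN mL⁻¹).
Equivalently `K = −ln(1 − f)/V` with `f = 1 − N/N0` the frozen fraction; the
identity is asserted to 1e−9 across both code paths in the tests. Where
`N(T) = 0` the estimator diverges; `K` is left *undefined* there rather than
infinite, and the spectrum records the warmest such temperature as its
censoring point. Headline spectra pool all plates (`N0 = 235` for the default
5 × 47 geometry); per-plate spectra are available through the same API.

**Onset** is the warmest grid temperature with at least one frozen droplet.
**T50** is the temperature where `f` crosses 1/2, linearly interpolated
between the bracketing grid points (exact grid values are returned
unmodified). Both are `None`, never a number, when undefined — a fully
censored assay has no onset; an assay where fewer than half the droplets
froze has no T50.

## Confidence bounds on K

The assay observes a binomial draw: each droplet is independently unfrozen at
`T` with probability `p = exp(−V·K_true(T))`. Bounds on `K` are therefore
exact Clopper–Pearson (beta-quantile) bounds on `p`, pushed through the
monotone transform `K = −ln(p)/V`. When no droplet has frozen the lower bound
is exactly 0; when all have frozen the upper bound is `+inf` and only the
lower bound is reported. At the default geometry (`n = 235`, `f ≈ 0.3`) the
exactly computed coverage of the nominal 95% interval is 95.5% (Clopper–
Pearson is conservative by construction); the calibration driver and the
acceptance suite verify the Monte-Carlo coverage against this exact value.

## Treatment comparison

Treatments are compared pairwise against the untreated (crude) assay of the
same sample:

- **onset decrease** = onset(control) − onset(treated), positive when the
  treatment removed the warmest-active nuclei;
- **ΔT50** = T50(control) − T50(treated), same sign convention;
- **percent sensitive** at reference temperatures (default −6, −8, −10 °C),
  computed from the *cumulative* concentrations, matching how such tables are
  conventionally reported. Raw values can leave [0, 100] through sampling
  noise (treated K exceeding control K); the clamped copy used in headline
  tables is clipped, the raw value is retained. The quantity is undefined
  where the control has no activity yet (`K = 0`), and flagged where the
  treated spectrum is censored (`N = 0`).

Two significance assessments of the T50 shift are always reported together:
a Welch two-sample test on the per-droplet freezing temperatures (censored
droplets carry no numeric temperature and are excluded from this test only),
and a percentile bootstrap — droplets resampled with replacement within each
group, ΔT50 recomputed per resample (B = 2000 by default, seed mandatory),
and the two-sided percentile p-value computed with add-one correction,
`p = min(1, 2·min(1+#{Δ*≤0}, 1+#{Δ*≥0})/(B+1))`. The correction makes the
test slightly conservative, so its null rejection rate sits just below the
nominal α; the calibration driver measures ≈5% at α = 0.05 over
same-scenario pairs. The bootstrap's T50 is computed by a vectorised routine
that reproduces the curve-based estimator exactly (property-tested), so the
two code paths cannot drift apart. Multi-treatment families can be adjusted
with the provided Holm helper; compact letter displays are deliberately not
implemented (no unambiguous convention), pairwise tests with Holm adjustment
take their place.

## The simulator

Per droplet, each IN class contributes `Poisson(c·V)` nuclei; each nucleus
draws a characteristic temperature from the class's Gaussian, truncated above
at 0 °C (the simplest two-parameter family that produces the narrow warm
modes characteristic of biological nucleators; the distribution enters only
through its tail function and is pluggable). One additional
droplet-intrinsic *background* temperature per droplet models impurity
nucleation of particle-free water: Normal(−16, 0.8) truncated at −10 °C by
default, anchored to the onset a Milli-Q control typically shows near −15 °C.
The droplet freezes at the warmest of all draws and is censored below the
cold-stage floor (−20 °C in the presets, safely below the background's
3-sigma range).

The closed-form cumulative spectrum of a scenario is
`Λ(T) = Σᵢ cᵢ·Sᵢ(T)` with `Sᵢ` the class upper-tail probability. The expected
unfrozen fraction is `exp(−V·Λ(T))·P(bg < T)`, so the exact target of the
`K(T)` estimator is

```
K_true(T) = Λ(T) − ln P(bg < T) / V ,
```

which equals `Λ(T)` wherever the background cannot yet freeze droplets and
exceeds it below about −14 °C. Consistency checks compare `K̂` to `K_true`,
not to `Λ` alone — comparing to `Λ` inside the coldest part of the evaluation
window would fail by construction, a model-specification bias rather than an
estimator defect.

**Treatment operators.** Heating removes heat-sensitive classes outright (no
partial-attenuation knob in this version: the canonical INA-bacteria control
loses *all* activity above −10 °C after 100 °C/10 min, which total removal
reproduces). Filtration is a sharp size cutoff at the 220-nm pore diameter;
no retention-efficiency curve.

## Presets

Preset compositions are *illustrative*: concentrations are chosen in closed
form to land the simulated onsets, medians and sensitivity fractions in the
ranges reported for this kind of sample, not fitted to any dataset.

- `ps_control` — one heat-sensitive class, 400 IN mL⁻¹ ≈ 10^2.6,
  N(−4.0, 0.25 °C), 1000 nm. Gives onset ≈ −3.2 °C and `K(−5.6) ≈ 10^2.6`
  with a handful of droplets unfrozen (`235·e⁻⁴ ≈ 4`). The mode's sd is set
  so the probability of a single run's onset leaving [−3.6, −2.8] is ~10⁻³
  (analytic Poisson-max bound), keeping the preset's documented behaviour
  stable across seeds.
- `pure_water` — no classes. Its background sd is narrowed to 0.5 °C (scenario
  default 0.8 °C) so that a 235-droplet array initiates freezing below −14 °C
  in essentially every run, consistent with the ≈ −15 °C onsets of ultra-pure
  water controls; with sd 0.8 the maximum of 235 draws would sit near
  −13.9 °C, which no such control shows.
- `paper_like_rain` — a heat-sensitive bacterial class (15.7 mL⁻¹,
  N(−4.3, 0.6), 1000 nm) plus heat-resistant submicron classes at
  24 mL⁻¹ (N(−5.0, 0.5)) and 90 mL⁻¹ (N(−9.6, 0.8)), both 100 nm. Solved so
  that exactly ~40% of `Λ(−6 °C)` is heat-sensitive, crude T50 ≈ −9.3 °C,
  filtrate T50 ≈ −9.6 °C, onsets near −3 / −3.8 °C. The filtration ΔT50 this
  produces (~0.4 °C) is smaller than the 1.5–4 °C shifts real rain samples
  can show; reproducing those would require giving the >220-nm class
  substantial activity between −7 and −9 °C, which conflicts with holding the
  −6 °C heat-sensitive share at 40%. The preset resolves the conflict in
  favour of the sensitivity fraction.

## What the synthetic data does and does not show

The generator reproduces the counting statistics the analysis assumes —
Poisson loading, independent droplets, singular freezing, censoring — so
passing tests demonstrate correctness of the estimators *under the model*.
It does not emulate: time-dependence of nucleation (cooling-rate effects),
plate-position or thermal-gradient artefacts, droplet-volume variation,
partial heat attenuation, filter breakthrough, or between-aliquot
composition differences. Agreement on synthetic data therefore says nothing
about those failure modes in real assays.

## Numerical choices

- Grid arithmetic uses a 1e−9 temperature tolerance so events lying exactly
  on grid points count identically in every code path.
- Onset/T50/onset-decrease are reported at grid precision (outputs print
  temperatures to 0.1 °C, concentrations to 0.1 mL⁻¹, percentages as whole
  numbers, the conventional table format).
- `percent_sensitive` raises on `K_control ≤ 0` rather than returning NaN,
  so undefined table cells are an explicit decision of the caller.
- The estimator-consistency check uses a steep three-mode scenario (class sd
  0.1 °C): the frozen fraction then crosses the noisy low-`f` band between
  two grid points, so every evaluated grid point keeps ≥3σ of sampling slack
  against the 5% tolerance at n = 10,000 (computed analytically from the
  binomial variance of `ln p̂`, not tuned on realisations). A diffuse scenario
  would place grid points at `f ≈ 0.05`, where the relative sd of `K̂` is
  ~4.5% and a fixed-seed check would be a coin flip.
- Simulation sizes in tests and drivers (10,000 droplets for consistency and
  recovery, 500 assays for coverage, 200–400 pairs for bootstrap
  calibration) put Monte-Carlo error well below each tolerance while keeping
  a full run in tens of seconds.
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  treatment aliquots get independent child seeds via `SeedSequence.spawn`
  (physically distinct droplet sets). Identical scenario + seed reproduces
  byte-identical CSV output.

## Known limitations

- No time-dependent (stochastic / water-activity) nucleation modelling; the
  estimator and simulator are purely singular.
- Droplet volume is uniform within an assay; `K` spectra from mixed-volume
  arrays are out of scope.
- The Welch test treats per-droplet freezing temperatures as approximately
  normal within groups; for strongly multimodal samples the bootstrap is the
  more trustworthy of the two reported p-values.
- Curves are step functions of pooled counts; no smoothing or differential
  (per-degree) spectra.
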