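# dropfreeze

Analysis of immersion-mode **drop-freezing assays** — the cold-stage
experiment used to count ice nuclei (IN) in rainwater, bacterial suspensions
and other liquid samples — together with a **singular-model simulator** that
generates synthetic assays with the statistical structure the analysis
assumes.

## Who this is for

Researchers running droplet-array freezing experiments (atmospheric ice
nucleation, bioprecipitation, INA-bacteria screening) who need to turn
per-droplet freezing temperatures into cumulative IN concentration spectra,
onset and median freezing temperatures, and heat-/filtration-sensitivity
tables — and to test that pipeline end-to-end without real data.

## The model

An array of `N0` droplets of volume `V` (default 5 plates × 47 droplets of
10 μL) is cooled at a fixed rate; each droplet's freezing temperature is
recorded. With `N(T)` the cumulative number of droplets still unfrozen at
temperature `T`, the cumulative IN concentration is

```
K(T) = (1/V) · ln(N0 / N(T))        [IN mL⁻¹]
```

Under the singular (time-independent) hypothesis each nucleus has a
characteristic freezing temperature and droplets carry Poisson-distributed
numbers of nuclei, so `K(T)` estimates the concentration of nuclei active at
or above `T`. The package adds exact binomial (Clopper–Pearson) confidence
bounds on `K`, onset (warmest freezing event) and `T50` (grid-interpolated
median freezing temperature), and paired treatment comparisons: heating
(100 °C, 10 min) destroys proteinaceous nucleators, 0.22-μm filtration
removes particles larger than 220 nm, and

```
pct_sensitive(T*) = 100 · (K_control(T*) − K_treated(T*)) / K_control(T*)
```

quantifies what a treatment removed at reference temperatures (−6, −8,
−10 °C). Significance of the `T50` shift is assessed by a Welch test plus a
seeded percentile bootstrap.

The simulator draws, per droplet, Poisson(`c·V`) nuclei from each IN class
(Gaussian characteristic-temperature distribution truncated at 0 °C) plus one
droplet-intrinsic background temperature; the droplet freezes at the warmest
draw. Heat and filtration act as class-removal operators, so programmed
sensitivity fractions are known in closed form.

## Worked example

```sh
in-assay simulate --preset paper_like_rain --seed 7 -o drops.csv
in-assay analyze  --input drops.csv -o out/
in-assay compare  --input drops.csv --control crude --seed 11 -o out/
```

or equivalently, run the numbered drivers `analysis/01_simulate_assays.py` …
`04_method_calibration.py`. With the seeds used there, the rainwater-like
preset prints:

```
paper_like_rain  crude         onset   -3.4 degC, T50   -9.1 degC (235/235 frozen)
paper_like_rain  heat          onset   -4.4 degC, T50   -9.9 degC (235/235 frozen)
paper_like_rain  filtrate      onset   -3.6 degC, T50   -9.6 degC (235/235 frozen)
```

— freezing starts near −3.4 °C (warm, biological-looking activity), half the
array is frozen by about −9 °C, and heating shifts onset and median colder.
The comparison step then reports

```
paper_like_rain  heat          onset decrease 1.0 degC, dT50 +0.73 degC (boot p=0.010),
                               sensitive: 59% @ -6, 54% @ -8, 25% @ -10
```

i.e. at −6 °C roughly half of the cumulative IN concentration in this
235-droplet realisation was heat-labile (the scenario's programmed value is
40%; single-assay sampling noise at `N0 = 235` is of this order, which is why
the recovery checks in the test suite use 10,000 droplets). A dense
INA-bacteria control preset (`ps_control`) freezes at −3.4 °C with
~10^2.6 IN mL⁻¹ at −5.6 °C and loses all activity above −10 °C when heated;
the `pure_water` preset first freezes near −15 °C.

Running the drivers writes their tables under `results/`: droplet CSVs,
spectrum and truth TSVs, `summary.tsv`, `comparison.tsv` and
`calibration.json` (with the driver seeds: estimator max relative error 3.8%
at n = 10,000; CI coverage 96.6% empirical vs 95.5% exact; bootstrap null
rejection 5.5% at α = 0.05).

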