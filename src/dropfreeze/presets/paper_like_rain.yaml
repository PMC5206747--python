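# Rainwater-like mixture (illustrative composition, not a fitted one):
#   - bacterial_ina: heat-sensitive proteinaceous nucleators on intact cells
#     (>220 nm, removed by both heat and filtration), warm mode near -4.3 degC.
#   - submicron_warm: heat-resistant sub-220-nm nucleators active just below
#     -5 degC; these pass the filter and survive heating.
#   - submicron_cold: the dominant heat-resistant submicron population,
#     active around -9 to -10 degC.
# Concentrations solve, in closed form, for: a 40% heat-sensitive share of the
# cumulative spectrum at -6 degC, a crude-sample T50 near -9.3 degC and a
# filtrate T50 near -9.6 degC, with onsets near -3 (crude) and -3.8 (filtrate).
sample_id: paper_like_rain
droplet_volume: 0.01
n_droplets: 235
n_plates: 5
cooling_rate: 2.0
min_temp: -20.0
background:
  temp_mean: -16.0
  temp_sd: 0.8
  max_temp: -10.0
classes:
  - label: bacterial_ina
    concentration: 15.7
    temp_mean: -4.3
    temp_sd: 0.6
    heat_sensitive: true
    size_nm: 1000.0
  - label: submicron_warm
    concentration: 24.0
    temp_mean: -5.0
    temp_sd: 0.5
    heat_sensitive: false
    size_nm: 100.0
  - label: submicron_cold
    concentration: 90.0
    temp_mean: -9.6
    temp_sd: 0.8
    heat_sensitive: false
    size_nm: 100.0
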