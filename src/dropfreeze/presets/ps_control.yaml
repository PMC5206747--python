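# Dense ice-nucleation-active bacterial suspension (~1e8 cells/mL order).
# A single heat-sensitive proteinaceous class: ~400 IN/mL active near -4 degC,
# so nearly every 10-uL droplet carries several nuclei (Poisson mean 4) and
# freezing of the whole array completes by about -5.6 degC, where the
# cumulative spectrum saturates at ~10^2.6 IN/mL. Heating removes the class
# entirely; filtration (cells ~1 um) does the same.
sample_id: ps_control
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
  - label: ina_protein
    concentration: 400.0
    temp_mean: -4.0
    temp_sd: 0.25
    heat_sensitive: true
    size_nm: 1000.0
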