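# Particle-free ultra-pure water: no IN classes, droplets freeze on the
# intrinsic background alone. The background here is slightly narrower
# (sd 0.5 degC) than the generic scenario default so that a 235-droplet array
# initiates freezing below -14 degC in essentially every run, matching the
# ~-15 degC onsets reported for Milli-Q water on this kind of cold stage.
sample_id: pure_water
droplet_volume: 0.01
n_droplets: 235
n_plates: 5
cooling_rate: 2.0
min_temp: -20.0
background:
  temp_mean: -16.0
  temp_sd: 0.5
  max_temp: -10.0
classes: []
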