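# Baseline lymphatic pumping-rate presets (pumps/min) for the growth
# hormone mouse lines, and the default EMCCD acquisition parameters.

[camera]
fps = 5.0
read_noise_sd = 2.0
shot_noise = true
background_level = 100.0
bit_depth = 16

[presets.bGH]
mean_rate = 8.6
sd_rate = 0.7
n_default = 6

[presets.WT]
mean_rate = 6.8
sd_rate = 1.0
n_default = 6

[presets.GHA]
mean_rate = 6.4
sd_rate = 1.5
n_default = 6

[presets.GHRKO]
mean_rate = 4.7
sd_rate = 1.1
n_default = 6
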