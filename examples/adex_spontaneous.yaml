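# Spontaneous asynchronous-irregular activity of the AdEx network vs the
# second-order mean-field prediction.
# Run:  spikemf spontaneous --config examples/adex_spontaneous.yaml --out out/ --seed 1
model: adex
N: 2500
duration: 10000.0
nu_drive: 4.0
nu_i_values: [2, 4, 6, 8, 12, 16]
n_e: 10
tf_duration: 10000.0
tf_seeds: 2
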