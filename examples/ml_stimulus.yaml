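# Morris-Lecar network driven by the double-Gaussian stimulus: the
# excitatory input suppresses both populations (depolarization block).
# Run:  spikemf stimulus --config examples/ml_stimulus.yaml --out out/ --seed 1
model: ml
N: 2500
duration: 6000.0
nu_i_values: [2, 4, 8, 12]
n_e: 10
tf_duration: 5000.0
tf_seeds: 2
A: 2.0
t0: 2000.0
T1: 100.0
T2: 150.0
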