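# Reference effective-threshold polynomial coefficients (mV) for the
# Hodgkin-Huxley cell types (see adex_reference_thresholds.tsv note).
cell	P0	P_muV	P_sigmaV	P_tauV	P_muV2	P_sigmaV2	P_tauV2	P_muVsigmaV	P_muVtauV	P_sigmaVtauV
RS	-48.1	3.2	10.9	-0.32	0.98	1.1	-1.2e-3	-1.4	3.9	-0.11
FS	-51.2	1.8	-6.1	-0.86	1.6	-0.70	-11	-0.18	1.2	-1.2
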