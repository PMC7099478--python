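# Reference effective-threshold polynomial coefficients (mV) for the
# Morris-Lecar cell types (see adex_reference_thresholds.tsv note).
cell	P0	P_muV	P_sigmaV	P_tauV	P_muV2	P_sigmaV2	P_tauV2	P_muVsigmaV	P_muVtauV	P_sigmaVtauV
RS	339	-218	-570	-1204	41.2	970	1724	297	186	-155
FS	-0.615	-2.56	-17.6	-164	0.83	-55	108	-7.4	24.6	288
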