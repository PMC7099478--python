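# Reference effective-threshold polynomial coefficients (mV) for the
# adaptive exponential integrate-and-fire cell types, from the original
# calibration of this parameterization.  Tied to its own normalization
# convention; fresh fits need not reproduce these numbers.
cell	P0	P_muV	P_sigmaV	P_tauV	P_muV2	P_sigmaV2	P_tauV2	P_muVsigmaV	P_muVtauV	P_sigmaVtauV
RS	-49.8	5.06	-23.4	2.3	-0.41	10.5	-36.6	7.4	1.2	-40.7
FS	-51.5	4.0	-8.35	0.24	-0.50	1.43	-14.7	4.5	2.8	-15.3
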