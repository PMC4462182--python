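# Published qPCR standard-curve coefficients for the reference primer panel.
# Curves are Ct = slope * log10(copies) + intercept, fitted over
# 10^1..10^9 gene copies per microlitre.
# efficiency_printed: published % efficiency, 100*(10^(-1/slope) - 1),
# computed from the unrounded slope.
set_id	anneal_c	slope	slope_se	intercept	intercept_se	efficiency_printed	r2
P1&2	60	-3.19	0.12	37.79	0.60	105.6	0.9922
P4	60	-3.13	0.08	41.67	0.47	108.5	0.9949
P5	60	-3.45	0.03	39.41	0.17	94.8	0.9997
P6A	59	-3.19	0.05	39.65	0.21	105.6	0.9989
P6B	58	-3.39	0.07	40.43	0.38	97.1	0.9972
P7Aa	58	-3.13	0.05	36.96	0.27	108.4	0.9984
P7Ab	60	-3.09	0.11	37.66	0.69	110.9	0.9916
P7Ac	56	-3.48	0.04	39.01	0.20	93.8	0.9994
P7B	59	-3.15	0.07	39.06	0.41	107.9	0.9962
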