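assay	x_true_percent	k_mean	cv_percent
cDNA	100	0.705	0.42
cDNA	95	0.684	0.02
cDNA	90	0.657	0.33
cDNA	80	0.612	0.33
cDNA	70	0.584	0.07
cDNA	60	0.556	0.01
cDNA	50	0.522	0.38
cDNA	40	0.495	0.36
cDNA	30	0.459	3.17
cDNA	20	0.440	0.26
cDNA	10	0.414	0.47
cDNA	5	0.403	0.29
cDNA	0	0.420	2.98
gDNA	100	0.708	0.64
gDNA	95	0.695	1.12
gDNA	90	0.674	0.11
gDNA	80	0.634	0.55
gDNA	70	0.601	1.28
gDNA	60	0.581	0.07
gDNA	50	0.551	0.53
gDNA	40	0.527	0.08
gDNA	30	0.501	0.28
gDNA	20	0.475	0.72
gDNA	10	0.454	0.32
gDNA	5	0.434	0.04
gDNA	0	0.426	0.15
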