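query	reference	snps_per_aligned_bp
FF	FO	0.000413390
FF	FN	0.000388363
FF	I	0.000470852
FF	C	0.000349889
FF	F	0.000546697
FF	MS	0.000533935
FO	FF	0.000314511
FO	FN	0.000348281
FO	I	0.000434378
FO	C	0.000309330
FO	F	0.000486504
FO	MS	0.000502400
FN	FF	0.000319526
FN	FO	0.000370514
FN	I	0.000472350
FN	C	0.000359891
FN	F	0.000531350
FN	MS	0.000557107
I	FF	0.000287344
I	FO	0.000333024
I	FN	0.000314453
I	C	0.000306604
I	F	0.000462724
I	MS	0.000500130
C	FF	0.000356861
C	FO	0.000409450
C	FN	0.000387226
C	I	0.000479916
C	F	0.000491909
C	MS	0.000558566
F	FF	0.000102675
F	FO	0.000137919
F	FN	0.000125332
F	I	0.000182317
F	C	0.000112822
F	MS	0.000236819
MS	FF	0.000187104
MS	FO	0.000244045
MS	FN	0.000230092
MS	I	0.000334766
MS	C	0.000212052
MS	F	0.00060301
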