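position	gene	ref	alt	samples	frequencies	quality
1698	cox1	C	CAAA	mRDI02;mRDI03	0.089;0.85	13800
6364	cytb	CT	C	fRDI04;mRDI05	0.80;0.81	2150000000
10449	nd5	C	CT	fRDI01;fRDI04;fRDI05	0.11;0.10;0.11	2150000000
17619	cox3	AGCG	A	mRDI01	0.97	5980
17621	cox3	CG	C	mRDI01	0.99	99900
17624	cox3	C	CAT	mRDI01	0.99	5980
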