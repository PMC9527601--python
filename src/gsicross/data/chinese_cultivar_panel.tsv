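ksn_type	name	ploidy	period	S_C1	S_C2	S_C3	S_C4	S_C5	ksn_copia	ksn_null	KSN_W	ap2	bloom	flower
1	Old Blush	2	I	1	1	0	0	0	1	1	0	1	CF	D
1	Hume's Blush Tea-scented China	2	I	1	1	0	0	0	1	1	0	1	CF	D
1	Mutabilis	2	I	1	0	0	0	1	1	1	0	0	CF	S
2	Rosa chinensis	2	I	1	0	0	1	0	1	0	0	1	CF	D
2	Slater's Crimson China (x2)	2	I	1	0	1	0	0	1	0	0	1	CF	D
2	Slater's Crimson China (x3)	3	I	1	1	1	0	0	1	0	0	1	CF	D
3	Sanguinea	2	I	0	1	1	0	0	0	1	0	0	CF	S
4	Single white-eye	2	I	1	0	0	0	0	1	0	1	0	OF	S
4	Narrow-leaflet	2	I	1	0	0	0	0	1	0	1	1	OF	D
4	Major	2	I	0	0	1	1	0	1	0	1	1	OF	D
5	Fortune's Double Yellow	2	I	1	0	1	0	0	0	0	1	1	OF	D
5	Rosa odorata var. erubescens	2	I	1	0	1	0	0	0	0	1	1	OF	D
5	Parks' Yellow Tea-scented China	2	I	0	0	0	0	0	0	0	1	1	OF	D
5	Rosa multiflora Carnea	2	I	1	0	0	0	0	0	0	1	1	OF	D
5	Rosa odorata Double Light Yellow	2	I	0	1	0	0	0	0	0	1	1	OF	D
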