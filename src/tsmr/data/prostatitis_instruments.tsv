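SNP	EA	NEA	EAF	BETA	SE	P
rs10915225	T	G	0.605	0.169	0.035	1.06e-06
rs4953907	C	T	0.103	-0.266	0.057	2.64e-06
rs9789699	G	A	0.308	0.175	0.037	2.10e-06
rs114884055	A	G	0.017	0.643	0.138	3.23e-06
rs76569337	C	T	0.204	0.233	0.043	4.21e-08
rs117901033	T	C	0.012	0.841	0.168	5.83e-07
rs79554384	T	C	0.067	0.317	0.069	4.40e-06
rs79165844	A	C	0.117	0.246	0.053	4.11e-06
rs35521406	G	A	0.192	0.216	0.043	6.18e-07
rs66617371	T	C	0.377	0.163	0.035	3.90e-06
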