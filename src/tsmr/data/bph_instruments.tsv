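SNP	EA	NEA	EAF	BETA	SE	P
rs12027141	A	G	0.180	0.001	2.70e-04	1.90e-06
rs12131120	A	T	0.519	-0.001	2.08e-04	2.00e-08
rs4953671	T	G	0.329	-0.001	2.21e-04	1.30e-06
rs2556378	G	T	0.843	-0.002	2.83e-04	2.10e-09
rs11926963	T	C	0.218	0.001	2.55e-04	2.60e-06
rs13077048	T	A	0.427	0.001	2.11e-04	1.90e-06
rs35425714	A	C	0.282	0.001	2.37e-04	4.10e-07
rs1379553	G	A	0.208	-0.001	2.56e-04	3.10e-08
rs630231	T	C	0.904	0.002	3.52e-04	2.00e-07
rs380286	A	G	0.437	-0.002	2.08e-04	4.90e-19
rs9504961	T	C	0.682	-0.001	2.22e-04	8.70e-07
rs113360274	G	A	0.191	0.001	2.63e-04	1.70e-06
rs9348716	A	G	0.128	-0.002	3.11e-04	1.80e-11
rs2740817	T	C	0.227	0.001	2.47e-04	3.10e-06
rs10788160	A	G	0.251	0.002	2.38e-04	6.10e-19
rs12255539	A	G	0.191	0.002	2.63e-04	1.80e-11
rs4266963	C	T	0.758	-0.001	2.41e-04	6.90e-10
rs600231	G	A	0.314	-0.001	2.23e-04	3.30e-07
rs3116616	G	C	0.215	0.002	2.51e-04	4.20e-10
rs7162895	T	C	0.417	0.001	2.10e-04	3.30e-06
rs9958656	C	T	0.583	-0.001	2.10e-04	7.40e-08
rs11084596	C	T	0.384	-0.002	2.16e-04	5.60e-13
rs3213180	C	G	0.108	0.002	3.35e-04	2.80e-07
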