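subject_id	caries_status	decayed_surfaces	filled_surfaces	zygosity	filtered_reads	mapped_reads	percent_mapped
2011	CA	1	0	DZ	10404431	4690029	45.00
2012	CA	1	0	DZ	5048821	2354837	46.64
2051	CF	0	0	MZ	15163860	6133805	40.45
2052	CF	0	0	MZ	8491819	3268038	38.49
2061	CA	2	0	DZ	5800355	2923616	50.41
2062	CF	0	0	DZ	4998861	2226509	44.54
2125	CA	17	0	MZ	5073718	2840183	55.98
2126	CA	6	3	MZ	10255337	5437838	53.03
2169	CF	0	0	MZ	5972974	3424681	57.34
2170	CA	1	0	MZ	7949869	4376808	55.05
2191	CF	0	0	MZ	6787165	3702907	54.56
2192	CF	0	0	MZ	5722083	2966892	51.85
2225	CF	0	0	MZ	7297864	3168223	43.42
2226	CI	0	1	MZ	9301393	2330247	25.06
2233	CF	0	0	DZ	4126376	1797372	43.56
2234	CF	0	0	DZ	5318936	2206502	41.48
2241	CA	1	0	DZ	3397928	1915754	56.38
2242	CA	1	0	DZ	4145884	2601872	62.76
2269	CA	2	0	DZ	3734615	2510588	67.23
2270	CF	0	0	DZ	3417500	2042613	59.77
2283	CI	0	2	DZ	5031738	3139713	62.40
2284	CA	1	0	DZ	4358907	2199217	50.45
2309	CF	0	0	DZ	9571270	3922570	40.98
2310	CF	0	0	DZ	7731245	2351980	30.42
2354	CA	1	0	DZ	4077295	2275040	55.80
2355	CA	1	0	DZ	1073838	464318	43.24
2930	CF	0	0	DZ	3873870	2279747	58.85
2931	CA	3	0	DZ	4071273	2225255	54.65
2954	CA	15	2	DZ	7338017	3247379	44.26
2955	CA	9	2	DZ	10133068	4293062	42.37
2991	CA	1	0	DZ	5331302	3270152	61.34
2992	CF	0	0	DZ	3267126	1265071	38.72
3214	CF	0	0	MZ	4008044	1758551	43.87
3215	CA	1	0	MZ	6357380	3360013	52.85
3306	CA	1	0	DZ	3773687	2163623	57.34
3307	CF	0	0	DZ	3748232	2198571	58.65
4131	CA	1	0	DZ	3656778	2075715	56.77
4132	CF	0	0	DZ	6734529	4223948	62.73
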