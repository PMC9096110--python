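# SYNTHETIC physicochemical amino-acid distance matrix: Euclidean
# distance over the z-scored Chou property triple (hydrophobicity,
# hydrophilicity, side-chain mass), max-normalised. Constructed
# stand-in for the Schneider-Wrede distance matrix. v1
residue	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.0000	0.2303	0.5699	0.6072	0.5627	0.1114	0.4939	0.3498	0.6936	0.3257	0.4093	0.4137	0.2143	0.4919	0.9440	0.2143	0.2434	0.2352	0.8284	0.6474
C	0.2303	0.0000	0.5000	0.5085	0.3825	0.3273	0.2786	0.2496	0.5913	0.1923	0.2028	0.2656	0.1175	0.3155	0.8069	0.2004	0.0960	0.1735	0.6197	0.4237
D	0.5699	0.5000	0.0000	0.0990	0.7602	0.5777	0.4178	0.6966	0.1550	0.6539	0.5693	0.3009	0.4003	0.3122	0.4375	0.3748	0.4146	0.6404	0.9044	0.6940
E	0.6072	0.5085	0.0990	0.0000	0.7207	0.6301	0.3859	0.6830	0.1567	0.6428	0.5413	0.3161	0.4211	0.3007	0.4136	0.4188	0.4331	0.6426	0.8462	0.6449
F	0.5627	0.3825	0.7602	0.7207	0.0000	0.6733	0.3961	0.2420	0.8177	0.2403	0.2019	0.5449	0.4766	0.5258	0.9692	0.5743	0.4583	0.3383	0.2882	0.2205
G	0.1114	0.3273	0.5777	0.6301	0.6733	0.0000	0.5724	0.4594	0.7074	0.4370	0.5139	0.4609	0.2834	0.5476	0.9660	0.2441	0.3161	0.3458	0.9367	0.7500
H	0.4939	0.2786	0.4178	0.3859	0.3961	0.5724	0.0000	0.4264	0.4421	0.3712	0.2356	0.1933	0.2925	0.1366	0.5910	0.3537	0.2573	0.4150	0.5110	0.2889
I	0.3498	0.2496	0.6966	0.6830	0.2420	0.4594	0.4264	0.0000	0.7925	0.0660	0.2014	0.4942	0.3386	0.5169	1.0000	0.4290	0.3403	0.1165	0.5294	0.4091
K	0.6936	0.5913	0.1550	0.1567	0.8177	0.7074	0.4421	0.7925	0.0000	0.7443	0.6378	0.3491	0.5074	0.3284	0.2828	0.4859	0.5067	0.7450	0.9170	0.7107
L	0.3257	0.1923	0.6539	0.6428	0.2403	0.4370	0.3712	0.0660	0.7443	0.0000	0.1574	0.4357	0.2910	0.4593	0.9476	0.3821	0.2850	0.0988	0.5187	0.3759
M	0.4093	0.2028	0.5693	0.5413	0.2019	0.5139	0.2356	0.2014	0.6378	0.1574	0.0000	0.3526	0.2816	0.3472	0.8180	0.3795	0.2637	0.2329	0.4317	0.2513
N	0.4137	0.2656	0.3009	0.3161	0.5449	0.4609	0.1933	0.4942	0.3491	0.4357	0.3526	0.0000	0.2151	0.0945	0.5498	0.2187	0.1852	0.4361	0.6976	0.4737
P	0.2143	0.1175	0.4003	0.4211	0.4766	0.2834	0.2925	0.3386	0.5074	0.2910	0.2816	0.2151	0.0000	0.2837	0.7460	0.1012	0.0588	0.2550	0.7051	0.4994
Q	0.4919	0.3155	0.3122	0.3007	0.5258	0.5476	0.1366	0.5169	0.3284	0.4593	0.3472	0.0945	0.2837	0.0000	0.4972	0.3066	0.2525	0.4784	0.6445	0.4225
R	0.9440	0.8069	0.4375	0.4136	0.9692	0.9660	0.5910	1.0000	0.2828	0.9476	0.8180	0.5498	0.7460	0.4972	0.0000	0.7323	0.7304	0.9673	0.9905	0.8090
S	0.2143	0.2004	0.3748	0.4188	0.5743	0.2441	0.3537	0.4290	0.4859	0.3821	0.3795	0.2187	0.1012	0.3066	0.7323	0.0000	0.1227	0.3332	0.7966	0.5854
T	0.2434	0.0960	0.4146	0.4331	0.4583	0.3161	0.2573	0.3403	0.5067	0.2850	0.2637	0.1852	0.0588	0.2525	0.7304	0.1227	0.0000	0.2614	0.6753	0.4653
V	0.2352	0.1735	0.6404	0.6426	0.3383	0.3458	0.4150	0.1165	0.7450	0.0988	0.2329	0.4361	0.2550	0.4784	0.9673	0.3332	0.2614	0.0000	0.6174	0.4670
W	0.8284	0.6197	0.9044	0.8462	0.2882	0.9367	0.5110	0.5294	0.9170	0.5187	0.4317	0.6976	0.7051	0.6445	0.9905	0.7966	0.6753	0.6174	0.0000	0.2242
Y	0.6474	0.4237	0.6940	0.6449	0.2205	0.7500	0.2889	0.4091	0.7107	0.3759	0.2513	0.4737	0.4994	0.4225	0.8090	0.5854	0.4653	0.4670	0.2242	0.0000
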