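# SYNTHETIC scale-family tables: deterministic rotated PCA scores of a
# 20x10 physicochemical property matrix (Eisenberg hydrophobicity,
# Hopp-Woods hydrophilicity, side-chain mass, Grantham c/p/v,
# Kyte-Doolittle hydropathy, Chou-Fasman Pa/Pb/Pturn). Constructed
# stand-ins matching the published dimensionalities of the Cruciani,
# FASGAI, T-scale, VHSE, ProtFP, ST-scale and MS-WHIM families. v1
residue	Crucian1	Crucian2	Crucian3	fasgai1	fasgai2	fasgai3	fasgai4	fasgai5	fasgai6	tscales1	tscales2	tscales3	tscales4	tscales5	vhsescales1	vhsescales2	vhsescales3	vhsescales4	vhsescales5	vhsescales6	vhsescales7	vhsescales8	protFP1	protFP2	protFP3	protFP4	protFP5	protFP6	protFP7	protFP8	stscales1	stscales2	stscales3	stscales4	stscales5	stscales6	stscales7	stscales8	mswhimscore1	mswhimscore2	mswhimscore3
A	1.69	-1.197	0.655	0.467	-1.384	-1.183	-0.276	0.994	-0.88	-1.617	0.187	-0.166	0.357	-1.514	1.208	0.366	-0.58	0.398	-0.306	1.985	0.618	0.776	1.04	1.766	0.861	-1.143	-1.205	-0.141	0.794	0.105	-0.87	0.128	0.076	-0.081	-1.938	0.228	0.599	1.542	-0.529	-1.305	1.277
C	1.6	1.369	-0.539	-0.904	1.175	1.034	0.679	-1.709	0.428	-1.422	1.815	-1.131	0.453	0.492	1.434	1.427	0.397	-0.813	2.285	-1.013	-1.755	0.164	-3.032	0.984	0.955	0.764	0.257	-0.247	-0.988	1.257	-0.149	0.378	1.393	2.126	-0.689	1.247	-0.268	-0.718	-0.081	1.521	-0.644
D	0.883	-0.059	0.929	0.751	0.422	-0.81	0.039	0.071	-1.207	-1.642	-1.926	-0.195	-1.38	1.622	-0.319	0.172	0.636	-1.507	0.43	1.08	0.499	0.774	0.216	1.248	-1.355	1.645	1.231	0.571	1.401	-0.101	-2.395	0.285	-0.805	1.188	1.419	-1.402	-1.12	-0.253	-1.613	1.763	0.433
E	1.334	-1.184	0.805	1.098	-1.332	-1.238	-0.299	-0.544	-2.419	-0.963	-1.087	-0.765	-1.117	1.115	-1.278	-0.018	0.28	-0.889	-1.055	2.18	-0.462	1.021	1.817	0.85	-1.711	-0.192	0.51	1.432	1.032	0.711	-1.012	0.488	-2.27	0.539	0.024	-2.142	-1.29	0.838	-2.099	-0.729	0.058
F	-1.063	0.105	-0.788	-0.362	-0.543	0.484	0.203	-0.301	0.781	1.752	1.63	0.092	1.644	-0.464	-0.687	-0.533	-0.752	1.054	-0.112	-0.672	-0.679	-0.982	0.063	-1.836	1.128	-1.57	-0.636	0.005	-0.768	0.569	2.165	-0.632	-0.052	-1.414	-1.637	0.863	0.482	-0.266	1.541	-1.91	-1.259
G	0.819	0.122	0.642	0.772	1.544	-0.62	0.301	1.312	0.596	-2.315	-1.166	-0.057	-0.951	-0.413	2.199	1.039	0.576	-0.061	1.474	0.704	1.718	-0.103	-0.727	2.473	0.763	1.626	0.275	-1.346	1.065	-0.363	-2.595	0.176	1.618	1.254	0.45	0.514	1.383	-0.472	-0.231	2.432	1.642
H	-0.285	-0.101	-0.553	0.275	0.384	0.141	-0.268	-0.093	-0.764	0.625	-0.845	-0.224	-0.53	0.259	-0.643	-0.158	0.647	-0.501	-0.82	-0.058	0.151	-0.313	0.905	-0.361	-0.726	0.383	0.649	-0.041	-0.31	-0.075	-0.079	0.304	-0.978	-0.254	0.816	-0.644	0.097	0.077	-0.556	-0.193	-0.192
I	-0.534	0.283	-0.371	-0.922	-0.695	-0.342	-0.18	-0.175	1.241	0.693	2.296	0.805	1.648	-1.021	0.102	-0.285	-0.857	1.658	0.473	-0.702	-0.324	-0.033	-0.467	-0.952	1.245	-1.397	-1.551	0.201	-0.619	0.349	1.86	-0.976	0.845	-1.37	-1.944	1.278	0.599	0.351	1.599	-1.486	-0.902
K	-0.371	-0.476	0.968	0.461	-0.882	-0.542	-0.681	0.074	-0.727	0.302	-1.188	0.498	-1.39	0.956	-1.216	-0.652	-0.187	-0.124	-1.282	0.509	0.122	0.789	1.29	-0.259	-1.802	0.426	0.044	1.234	0.742	-0.525	-0.3	0.394	-1.002	-0.242	1.507	-1.876	-1.384	0.239	-1.13	0.32	0.35
L	-0.207	-0.174	-0.171	-0.258	-1.059	0.048	-0.069	0.036	0.738	0.705	1.818	0.187	1.368	-0.912	0.159	-0.173	-1.163	1.276	0.043	-0.06	-0.495	-0.343	-0.005	-0.785	1.348	-1.596	-1.383	0.081	-0.312	0.529	1.565	-0.387	0.569	-1.062	-2.082	0.809	0.406	0.245	1.178	-1.654	-0.423
M	0.091	-0.854	0.002	0.195	-1.641	0.127	0.177	0.006	-0.256	0.776	1.019	-0.358	1.183	-0.66	-0.455	-0.334	-1.08	0.57	-0.708	0.763	-0.707	-0.266	0.744	-0.761	0.815	-2.035	-0.795	0.243	-0.024	0.533	1.333	-0.131	-0.513	-0.769	-1.946	0.201	-0.071	0.505	0.564	-2.29	-0.244
N	0.142	0.662	-0.21	0.078	1.626	0.274	-0.09	0.253	-0.253	-0.724	-1.629	0.026	-1.077	0.764	0.41	0.34	0.995	-1.394	0.5	-0.509	0.808	-0.008	-0.491	0.689	-0.661	2.071	1.201	-0.595	0.221	-0.594	-1.798	0.373	0.182	0.846	1.908	-0.311	-0.077	-0.485	-0.751	2.09	0.445
P	-0.118	-0.013	0.701	1.143	1.389	0.03	0.897	1.191	0.413	-0.927	-1.579	-0.65	-0.863	0.016	1.262	0.32	0.645	0.099	0.663	0.751	1.109	-0.966	-0.068	1.421	0.561	1.011	1.037	-1.011	0.76	-0.31	-1.645	0.484	0.629	1.017	0.879	0.227	1.188	-1.214	-0.242	1.829	1.132
Q	0.171	-0.206	-0.34	-0.339	-0.131	0.072	-0.517	-0.324	-0.722	0.118	-0.63	0.241	-0.577	0.089	-0.565	0.015	0.422	-0.869	-0.802	-0.267	0.057	0.699	0.324	-0.091	-1.163	0.347	0.251	0.082	-0.247	-0.478	-0.199	0.106	-0.628	0.113	1.0	-0.613	-0.579	0.779	-0.602	-0.092	0.168
R	-0.721	0.273	0.922	-0.614	-0.593	0.23	-0.32	-0.444	-0.666	1.019	-1.068	0.405	-1.184	0.937	-1.343	-1.251	0.348	-0.285	-1.59	-0.499	-0.751	0.987	0.669	-0.748	-2.164	0.439	0.554	1.718	-0.355	-1.101	0.557	0.725	-1.222	0.026	2.605	-1.294	-1.956	0.084	-1.41	0.519	-0.108
S	1.137	0.318	0.353	0.377	1.026	-0.026	0.272	0.25	-0.183	-1.747	-0.734	-0.539	-0.738	0.278	1.338	0.854	0.507	-0.818	1.094	0.422	0.385	0.138	-0.854	1.714	0.248	1.324	0.554	-0.558	0.518	0.079	-1.876	0.521	0.746	1.445	0.453	0.104	0.197	-0.375	-0.766	1.83	0.842
T	0.204	0.253	-0.114	-0.482	0.492	-0.233	-0.197	0.073	0.261	-0.522	0.072	0.34	-0.215	-0.543	0.652	0.259	0.473	0.155	0.228	-0.377	0.386	0.428	-0.406	0.639	-0.079	0.445	-0.19	-0.279	-0.32	-0.381	-0.278	-0.085	0.543	0.208	0.402	0.44	0.439	0.375	-0.046	0.534	0.319
V	-0.166	0.283	-0.137	-1.318	-0.685	-0.643	-0.305	0.127	1.185	0.057	2.011	1.162	1.526	-1.452	0.57	-0.265	-0.655	1.492	0.491	-0.669	0.088	0.616	-0.626	-0.301	1.073	-1.164	-1.675	0.118	-0.544	-0.226	1.333	-1.035	1.103	-1.164	-1.586	1.534	0.574	0.89	1.358	-1.177	-0.394
W	-2.293	-0.038	-1.675	0.075	-0.02	1.81	0.315	-0.62	0.908	3.371	0.747	-0.142	1.233	0.339	-1.895	-0.546	-0.66	0.133	-0.791	-1.553	-0.734	-1.994	0.159	-3.366	0.471	-1.264	0.388	-0.731	-1.024	0.457	2.614	-0.564	-0.561	-1.456	-0.485	0.183	0.28	-1.019	2.061	-1.853	-1.538
Y	-2.316	0.634	-1.081	-0.492	0.905	1.385	0.32	-0.178	1.526	2.46	0.259	0.472	0.608	0.114	-0.933	-0.577	0.01	0.425	-0.215	-2.015	-0.038	-1.384	-0.551	-2.324	0.195	-0.12	0.483	-0.741	-1.023	-0.436	1.769	-0.552	0.324	-0.953	0.845	0.655	0.501	-1.122	1.753	-0.148	-0.96
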