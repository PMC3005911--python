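# SYNTHETIC direction-sensitive amino-acid exchangeability matrix.
# This is a synthetic stand-in constructed from the Grantham (1974)
# polarity scale: EX(source->dest) = exp(-(|dP| + 0.3*dP)/8) with
# dP = polarity(dest) - polarity(source). Higher = more exchangeable
# (conservative); lower = more radical. Replace with an experimental
# matrix via the exchangeability_path config key for real analyses.
# rows = source amino acid, columns = destination amino acid.
source	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	NA	0.7965	0.4510	0.5054	0.7759	0.8639	0.6881	0.7759	0.5945	0.7558	0.8106	0.5662	0.9913	0.6771	0.6771	0.8363	0.9220	0.8249	0.7896	0.8468
C	0.6554	NA	0.2956	0.3312	0.9741	0.5662	0.4510	0.9741	0.3897	0.9489	0.9680	0.3711	0.6661	0.4437	0.4437	0.5481	0.6043	0.9371	0.9913	0.8925
D	0.6513	0.5188	NA	0.9406	0.5054	0.7047	0.7965	0.5054	0.8618	0.4923	0.5280	0.8847	0.6456	0.8035	0.8035	0.7171	0.6805	0.5373	0.5143	0.5516
E	0.6925	0.5516	0.8925	NA	0.5373	0.7492	0.8468	0.5373	0.9162	0.5234	0.5613	0.9406	0.6864	0.8543	0.8543	0.7624	0.7234	0.5712	0.5468	0.5864
F	0.6242	0.9524	0.2815	0.3155	NA	0.5393	0.4296	1.0000	0.3711	0.9741	0.9220	0.3535	0.6344	0.4226	0.4226	0.5220	0.5755	0.8925	0.9680	0.8500
G	0.9243	0.7362	0.5220	0.5849	0.7171	NA	0.7965	0.7171	0.6881	0.6985	0.7492	0.6554	0.9162	0.7837	0.7837	0.9680	0.9656	0.7624	0.7298	0.7827
H	0.8177	0.6513	0.6554	0.7344	0.6344	0.8847	NA	0.6344	0.8639	0.6180	0.6628	0.8228	0.8106	0.9839	0.9839	0.9003	0.8543	0.6745	0.6456	0.6925
I	0.6242	0.9524	0.2815	0.3155	1.0000	0.5393	0.4296	NA	0.3711	0.9741	0.9220	0.3535	0.6344	0.4226	0.4226	0.5220	0.5755	0.8925	0.9680	0.8500
K	0.7558	0.6020	0.7586	0.8500	0.5864	0.8177	0.9243	0.5864	NA	0.5712	0.6126	0.9524	0.7492	0.9324	0.9324	0.8321	0.7896	0.6234	0.5968	0.6400
L	0.5945	0.9071	0.2681	0.3004	0.9524	0.5136	0.4091	0.9524	0.3535	NA	0.8781	0.3366	0.6043	0.4025	0.4025	0.4972	0.5481	0.8500	0.9220	0.8096
M	0.6771	0.9827	0.3054	0.3422	0.9572	0.5849	0.4659	0.9572	0.4025	0.9324	NA	0.3834	0.6881	0.4584	0.4584	0.5662	0.6242	0.9680	0.9741	0.9220
N	0.7362	0.5864	0.7965	0.8925	0.5712	0.7965	0.9003	0.5712	0.9741	0.5564	0.5968	NA	0.7298	0.9082	0.9082	0.8106	0.7691	0.6073	0.5813	0.6234
P	0.9839	0.8035	0.4437	0.4972	0.7827	0.8500	0.6771	0.7827	0.5849	0.7624	0.8177	0.5571	NA	0.6661	0.6661	0.8228	0.9071	0.8321	0.7965	0.8543
Q	0.8106	0.6456	0.6661	0.7464	0.6289	0.8770	0.9913	0.6289	0.8781	0.6126	0.6570	0.8363	0.8035	NA	1.0000	0.8925	0.8468	0.6686	0.6400	0.6864
R	0.8106	0.6456	0.6661	0.7464	0.6289	0.8770	0.9913	0.6289	0.8781	0.6126	0.6570	0.8363	0.8035	1.0000	NA	0.8925	0.8468	0.6686	0.6400	0.6864
S	0.9082	0.7234	0.5393	0.6043	0.7047	0.9827	0.8228	0.7047	0.7109	0.6864	0.7362	0.6771	0.9003	0.8096	0.8096	NA	0.9489	0.7492	0.7171	0.7691
T	0.9572	0.7624	0.4892	0.5481	0.7427	0.9371	0.7464	0.7427	0.6448	0.7234	0.7759	0.6142	0.9489	0.7344	0.7344	0.9071	NA	0.7896	0.7558	0.8106
V	0.6994	0.9656	0.3155	0.3535	0.9406	0.6043	0.4813	0.9406	0.4158	0.9162	0.9827	0.3960	0.7109	0.4735	0.4735	0.5849	0.6448	NA	0.9572	0.9524
W	0.6448	0.9839	0.2908	0.3259	0.9827	0.5571	0.4437	0.9827	0.3834	0.9572	0.9524	0.3651	0.6554	0.4366	0.4366	0.5393	0.5945	0.9220	NA	0.8781
Y	0.7344	0.9406	0.3312	0.3711	0.9162	0.6344	0.5054	0.9162	0.4366	0.8925	0.9572	0.4158	0.7464	0.4972	0.4972	0.6142	0.6771	0.9741	0.9324	NA
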