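# Grantham (1974) amino-acid physicochemical distance matrix,
# normalized to maximum 1 (v1). Symmetric, zero diagonal.
residue	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.000000	0.909692	0.586617	0.497814	0.525192	0.279878	0.398828	0.436935	0.492488	0.448712	0.393910	0.515100	0.125369	0.423401	0.519049	0.462453	0.270679	0.300567	0.689144	0.520559
C	0.909692	0.000000	0.716424	0.790425	0.953472	0.738151	0.810976	0.920170	0.940367	0.921006	0.912261	0.647345	0.786475	0.719487	0.837530	0.520952	0.694756	0.892099	1.000000	0.903725
D	0.586617	0.716424	0.000000	0.208081	0.823494	0.437425	0.378975	0.784097	0.473296	0.801247	0.746524	0.107320	0.503398	0.285892	0.446970	0.305421	0.396880	0.709142	0.888926	0.746108
E	0.497814	0.790425	0.208081	0.000000	0.654089	0.456479	0.190305	0.625866	0.265289	0.645370	0.588186	0.190607	0.437254	0.136562	0.251998	0.372209	0.305563	0.565997	0.710290	0.572754
F	0.525192	0.953472	0.823494	0.654089	0.000000	0.714330	0.466477	0.099257	0.476489	0.101809	0.133082	0.737593	0.530537	0.539213	0.452657	0.722179	0.479836	0.232948	0.184991	0.100809
G	0.279878	0.738151	0.437425	0.456479	0.714330	0.000000	0.454993	0.631728	0.589926	0.642331	0.592198	0.370148	0.194200	0.406631	0.583727	0.257822	0.275965	0.507493	0.857381	0.685411
H	0.398828	0.810976	0.378975	0.190305	0.466477	0.454993	0.000000	0.440084	0.151159	0.460403	0.402794	0.318875	0.355833	0.112352	0.134442	0.414884	0.218102	0.391360	0.534427	0.388727
I	0.436935	0.920170	0.784097	0.625866	0.099257	0.631728	0.440084	0.000000	0.474021	0.022649	0.047214	0.694684	0.444929	0.506461	0.455241	0.661487	0.416505	0.138126	0.282362	0.154167
K	0.492488	0.940367	0.473296	0.265289	0.476489	0.589926	0.151159	0.474021	0.000000	0.496055	0.440796	0.437963	0.479161	0.248310	0.121308	0.562284	0.362662	0.452493	0.510512	0.395529
L	0.448712	0.921006	0.801247	0.645370	0.101809	0.642331	0.460403	0.022649	0.496055	0.000000	0.066724	0.710624	0.456126	0.524539	0.475271	0.672129	0.430832	0.148276	0.284474	0.166435
M	0.393910	0.912261	0.746524	0.588186	0.133082	0.592198	0.402794	0.047214	0.440796	0.066724	0.000000	0.658477	0.403965	0.470694	0.427492	0.629140	0.378050	0.100399	0.310861	0.164314
N	0.515100	0.647345	0.107320	0.190607	0.737593	0.370148	0.318875	0.694684	0.437963	0.710624	0.658477	0.000000	0.420584	0.213434	0.397056	0.215708	0.302172	0.619874	0.810691	0.663500
P	0.125369	0.786475	0.503398	0.437254	0.530537	0.194200	0.355833	0.444929	0.479161	0.456126	0.403965	0.420584	0.000000	0.350509	0.479165	0.342190	0.175234	0.316224	0.683986	0.511356
Q	0.423401	0.719487	0.285892	0.136562	0.539213	0.406631	0.112352	0.506461	0.248310	0.524539	0.470694	0.213434	0.350509	0.000000	0.199727	0.318143	0.191754	0.449359	0.607403	0.460824
R	0.519049	0.837530	0.446970	0.251998	0.452657	0.583727	0.134442	0.455241	0.121308	0.475271	0.427492	0.397056	0.479165	0.199727	0.000000	0.509479	0.331080	0.446893	0.472520	0.359707
S	0.462453	0.520952	0.305421	0.372209	0.722179	0.257822	0.414884	0.661487	0.562284	0.672129	0.629140	0.215708	0.342190	0.318143	0.509479	0.000000	0.269399	0.573953	0.823734	0.667596
T	0.270679	0.694756	0.396880	0.305563	0.479836	0.275965	0.218102	0.416505	0.362662	0.430832	0.378050	0.302172	0.175234	0.191754	0.331080	0.269399	0.000000	0.324200	0.598593	0.430335
V	0.300567	0.892099	0.709142	0.565997	0.232948	0.507493	0.391360	0.138126	0.452493	0.148276	0.100399	0.619874	0.316224	0.449359	0.446893	0.573953	0.324200	0.000000	0.410350	0.255002
W	0.689144	1.000000	0.888926	0.710290	0.184991	0.857381	0.534427	0.282362	0.510512	0.284474	0.310861	0.810691	0.683986	0.607403	0.472520	0.823734	0.598593	0.410350	0.000000	0.173136
Y	0.520559	0.903725	0.746108	0.572754	0.100809	0.685411	0.388727	0.154167	0.395529	0.166435	0.164314	0.663500	0.511356	0.460824	0.359707	0.667596	0.430335	0.255002	0.173136	0.000000
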