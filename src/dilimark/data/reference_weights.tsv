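gene	lasso	svm_linear	random_forest	neural_net	gbm	decision_tree	total
DDIT3	0.914222	1	1	0.220019	1	1	5.134241
GADD45A	1	0.701511	0.595707	0.857692	0.138689	0.292928	3.586528
RBM24	0.032375	0.891609	0.762935	1	0.616145	0.217391	3.520456
SLC3A2	0.846442	0.62703	0.562559	0.690844	0.241597	0.432583	3.401055
IFRD1	0	0.542098	0.524983	0.365069	0.038438	0.26087	1.731457
GDF15	0	0.3516	0.383822	0.786062	0.00509	0.032059	1.558633
JMY	0	0.353108	0.433204	0.305061	0.123692	0.26087	1.475935
UPP1	0	0.512905	0.463177	0.396437	0.053665	0.032059	1.458243
CPEB4	0	0.165532	0.26272	0.743079	0.004831	0	1.176162
PPP1R15A	0	0.079463	0.222258	0.823152	0.006435	0	1.131307
PIM1	0	0.15555	0.307897	0.231436	0.113818	0.224411	1.033112
LDLR	0	0.055148	0.191678	0.572498	0.006348	0.064117	0.889789
MAFF	0	0.124409	0.208423	0.449151	0.030866	0	0.812849
TRIB3	0	0.180949	0.24403	0.349341	0.019652	0	0.793972
ASNS	0	0.25119	0.29182	0.183775	0.02987	0	0.756656
SLC7A11	0	0.141399	0.208826	0.348854	0.008297	0	0.707376
SLC20A1	0	0.308733	0.34717	0.017776	0.029455	0	0.703135
MTHFD2	0	0.079061	0.176848	0.379338	0.005218	0	0.640465
GPCPD1	0	0.204886	0.331006	0.017325	0.046414	0	0.599631
NR1D2	0	0.233607	0.284661	0.038773	0.021109	0	0.57815
GADD45B	0	0.124042	0.235818	0.142752	0.027562	0	0.530174
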