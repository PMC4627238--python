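gene	expr_mean_low	expr_mean_high	expr_fold_change	expr_p	meth_mean_low	meth_mean_high	meth_fold_change	meth_p
GAS8	0.8874	1.3309	0.6668	0.0001	0.3448	0.2098	1.6432	0.0001
MGMT	1.8678	2.5767	0.7249	0.0000	0.1869	0.1122	1.6662	0.0007
CLN8	1.8429	2.3516	0.7837	0.0016	0.2118	0.1093	1.9379	0.0010
LMBR1	2.4871	2.8192	0.8822	0.0046	0.2236	0.1321	1.6932	0.0014
BNIP3	1.4292	1.7909	0.7980	0.0020	0.2122	0.1149	1.8470	0.0016
LY6E	0.9572	1.4992	0.6385	0.0003	0.2377	0.1251	1.8994	0.0020
ZFP28	1.4123	2.1194	0.6663	0.0018	0.2386	0.1653	1.4439	0.0022
GLT1D1	2.7025	3.9834	0.6784	0.0001	0.3092	0.2020	1.5309	0.0030
TYMS	2.6947	3.6345	0.7414	0.0029	0.2429	0.1472	1.6504	0.0035
ANKRD11	2.4346	2.7741	0.8776	0.0011	0.1684	0.0889	1.8943	0.0036
PANK2	1.4702	1.7699	0.8307	0.0021	0.1469	0.0663	2.2139	0.0037
TUBB2A	1.9709	3.0462	0.6470	0.0000	0.3389	0.2299	1.4743	0.0045
PRKAR1B	0.9218	1.5021	0.6137	0.0002	0.2416	0.1342	1.8002	0.0048
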