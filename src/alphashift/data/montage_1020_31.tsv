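label	x	y	z
Fp1	-0.02944	0.08392	-0.00699
Fp2	0.02987	0.08490	-0.00708
F7	-0.07026	0.04247	-0.01142
F3	-0.05024	0.05311	0.04219
Fz	0.00031	0.05851	0.06646
F4	0.05184	0.05430	0.04081
F8	0.07304	0.04442	-0.01200
FC5	-0.07721	0.01864	0.02446
FC1	-0.03406	0.02601	0.07999
FC2	0.03478	0.02644	0.07881
FC6	0.07953	0.01994	0.02444
T7	-0.08416	-0.01602	-0.00935
C3	-0.06536	-0.01163	0.06436
Cz	0.00040	-0.00917	0.10024
C4	0.06712	-0.01090	0.06358
T8	0.08508	-0.01502	-0.00949
TP9	-0.08562	-0.04651	-0.04571
CP5	-0.07959	-0.04655	0.03095
CP1	-0.03551	-0.04729	0.09131
CP2	0.03838	-0.04707	0.09069
CP6	0.08332	-0.04610	0.03121
TP10	0.08616	-0.04704	-0.04587
P7	-0.07243	-0.07345	-0.00249
P3	-0.05301	-0.07879	0.05594
Pz	0.00032	-0.08111	0.08261
P4	0.05567	-0.07856	0.05656
P8	0.07306	-0.07307	-0.00254
PO9	-0.05491	-0.09804	-0.03547
O1	-0.02941	-0.11245	0.00884
O2	0.02984	-0.11216	0.00880
PO10	0.05499	-0.09809	-0.03554
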