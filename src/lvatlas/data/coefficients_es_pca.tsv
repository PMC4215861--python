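parameter	coefficient	se	std_coef	odds_ratio	ci_low	ci_high
Intercept	-16.8281	4.1446
Age	0.0467	0.0178	0.2629	1.0480	1.0120	1.0850
Sex	-0.4471	0.4698	-0.1232	0.6400	0.2550	1.6060
Height	0.0506	0.0245	0.2851	1.0520	1.0020	1.1040
Weight	-0.0306	0.0086	-0.3048	0.9700	0.9540	0.9860
SBP	0.0310	0.0114	0.3732	1.0320	1.0090	1.0550
DBP	-0.0239	0.0206	-0.1378	0.9760	0.9380	1.0170
mode1	0.0214	0.0018	1.8503	1.0220	1.0180	1.0250
mode2	0.0209	0.0030	0.7308	1.0210	1.0150	1.0270
mode3	0.0111	0.0026	0.3281	1.0110	1.0060	1.0160
mode4	0.0463	0.0049	1.1490	1.0470	1.0370	1.0580
mode5	-0.0011	0.0039	-0.0250	0.9990	0.9910	1.0060
mode6	-0.0126	0.0044	-0.2509	0.9870	0.9790	0.9960
mode7	0.0264	0.0043	0.4954	1.0270	1.0180	1.0350
mode8	0.0085	0.0046	0.1508	1.0090	0.9990	1.0180
mode9	-0.0245	0.0052	-0.3856	0.9760	0.9660	0.9860
mode10	0.0260	0.0063	0.3877	1.0260	1.0140	1.0390
mode11	0.0054	0.0067	0.0736	1.0050	0.9920	1.0190
mode12	-0.0242	0.0064	-0.3150	0.9760	0.9640	0.9890
mode13	-0.0022	0.0072	-0.0248	0.9980	0.9840	1.0120
mode14	0.0386	0.0077	0.4035	1.0390	1.0240	1.0550
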