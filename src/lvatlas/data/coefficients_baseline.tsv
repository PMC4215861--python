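parameter	coefficient	se	std_coef	odds_ratio	ci_low	ci_high
Intercept	-18.8662	1.9036
Age	0.0233	0.0085	0.1308	1.0240	1.0070	1.0410
Sex	0.4107	0.2263	0.1132	1.5080	0.9680	2.3500
Height	0.0943	0.0111	0.5316	1.0990	1.0750	1.1230
Weight	-0.0216	0.0046	-0.2148	0.9790	0.9700	0.9880
SBP	0.0045	0.0053	0.0536	1.0040	0.9940	1.0150
DBP	0.0002	0.0105	0.0010	1.0000	0.9800	1.0210
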