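parameter	coefficient	se	p	std_coef	odds_ratio	ci_low	ci_high
Intercept	-14.6045	2.9025	<.0001
Age	0.0246	0.0128	0.0538	0.1384	1.0250	1.0000	1.0510
Sex	-0.2043	0.3522	0.5619	-0.0563	0.8150	0.4090	1.6260
Height	0.0650	0.0176	0.0002	0.3664	1.0670	1.0310	1.1040
Weight	-0.0321	0.0068	<.0001	-0.3197	0.9680	0.9560	0.9810
SBP	0.0126	0.0080	0.1136	0.1515	1.0130	0.9970	1.0290
DBP	-0.0138	0.0158	0.3826	-0.0792	0.9860	0.9560	1.0170
EDV	-0.0245	0.0070	0.0005	-0.5374	0.9760	0.9630	0.9890
ESV	0.1175	0.0099	<.0001	2.0280	1.1250	1.1030	1.1470
MASS	-0.0185	0.0048	0.0001	-0.3894	0.9820	0.9730	0.9910
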