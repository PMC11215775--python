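frame_index	time_ps	dS	U_kJ_per_mol
0	0	0	0.5
1	0.001	0.0053886925099236576	0.49947842664027137
2	0.002	-0.0004765418896935644	0.49913177925217816
3	0.0030000000000000001	-0.0042077121105519831	0.49873683580156103
4	0.0040000000000000001	-0.0037195390642986025	0.49826617682851487
5	0.0050000000000000001	-0.0030815465343441454	0.49768686290973763
6	0.0060000000000000001	-0.0035315176759272981	0.49701950871979866
7	0.0070000000000000001	-0.0042059821060026941	0.49631151170381799
8	0.0080000000000000002	-0.0072662739103940598	0.49541853307752332
9	0.0090000000000000011	-0.0022249585688568422	0.49444062171636782
10	0.01	0.00038322242811461007	0.49349959009773969
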