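frame_index	time_ps	dS	U_kJ_per_mol
0	0	0	0.5
1	0.001	-0.0094846903236059186	0.50050565480437426
2	0.002	0.0042518249958325297	0.50090016025250539
3	0.0030000000000000001	0.0056660123865046015	0.50133816408550114
4	0.0040000000000000001	0.0039281513446609729	0.5019982594264748
5	0.0050000000000000001	0.011838208680397326	0.50281888074055492
6	0.0060000000000000001	0.0077900454895505639	0.50383287089526974
7	0.0070000000000000001	0.0056133010626695946	0.50511459499455824
8	0.0080000000000000002	-0.0079248865516589207	0.5063149471697842
9	0.0090000000000000011	-0.0072313822061942619	0.50736251452028913
10	0.01	0.0030386348617451688	0.50837582144646454
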