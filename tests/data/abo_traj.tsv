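frame_index	time_ps	q0	q1
0	0	-0.5	1.5
1	0.001	-0.49947842664027137	1.4984114913089324
2	0.002	-0.49913177925217816	1.4967185170480204
3	0.0030000000000000001	-0.49873683580156103	1.4949631764145073
4	0.0040000000000000001	-0.49826617682851487	1.493336399834573
5	0.0050000000000000001	-0.49768686290973763	1.4915596911552482
6	0.0060000000000000001	-0.49701950871979866	1.4897044543989084
7	0.0070000000000000001	-0.49631151170381799	1.4878314235752865
8	0.0080000000000000002	-0.49541853307752332	1.4860143348981232
9	0.0090000000000000011	-0.49444062171636782	1.4841575267355074
10	0.01	-0.49349959009773969	1.4823175849516932
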