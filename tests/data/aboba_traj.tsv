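frame_index	time_ps	q0	q1
0	0	-0.5	1.5
1	0.001	-0.50050565480437426	1.501628425239613
2	0.002	-0.50090016025250539	1.5030984113551968
3	0.0030000000000000001	-0.50133816408550114	1.5045286629472447
4	0.0040000000000000001	-0.5019982594264748	1.5058793052576471
5	0.0050000000000000001	-0.50281888074055492	1.5071931530165117
6	0.0060000000000000001	-0.50383287089526974	1.5084796617922338
7	0.0070000000000000001	-0.50511459499455824	1.5098312420328366
8	0.0080000000000000002	-0.5063149471697842	1.5111974556393166
9	0.0090000000000000011	-0.50736251452028913	1.5124749958332282
10	0.01	-0.50837582144646454	1.5138852958653963
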