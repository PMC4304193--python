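study	case_event	case_total	control_event	control_total
1	11	270	25	630
2	244	1016	282	926
3	49	234	35	166
4	79	600	76	600
5	71	290	86	340
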