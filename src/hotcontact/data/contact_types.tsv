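# group_i	group_j	type	type_name
N_DON	N_DON	1	don_don
N_DON	O_ACC	0	hbond
N_DON	O_DA	0	hbond
N_DON	N_DA	0	hbond
N_DON	C_C	2	cc_on
N_DON	C_ON	4	con_on
N_DON	S	8	s_on
N_DON	PI	9	pi
N_DON	N_PRO	0	hbond
N_DON	WAT	10	wat_on
O_ACC	O_ACC	13	acc_acc
O_ACC	O_DA	0	hbond
O_ACC	N_DA	0	hbond
O_ACC	C_C	2	cc_on
O_ACC	C_ON	4	con_on
O_ACC	S	8	s_on
O_ACC	PI	9	pi
O_ACC	N_PRO	13	acc_acc
O_ACC	WAT	10	wat_on
O_DA	O_DA	0	hbond
O_DA	N_DA	0	hbond
O_DA	C_C	2	cc_on
O_DA	C_ON	4	con_on
O_DA	S	8	s_on
O_DA	PI	9	pi
O_DA	N_PRO	0	hbond
O_DA	WAT	10	wat_on
N_DA	N_DA	0	hbond
N_DA	C_C	2	cc_on
N_DA	C_ON	4	con_on
N_DA	S	8	s_on
N_DA	PI	9	pi
N_DA	N_PRO	0	hbond
N_DA	WAT	10	wat_on
C_C	C_C	3	cc_cc
C_C	C_ON	5	con_cc
C_C	S	7	s_c
C_C	PI	9	pi
C_C	N_PRO	2	cc_on
C_C	WAT	12	wat_c
C_ON	C_ON	6	con_con
C_ON	S	7	s_c
C_ON	PI	9	pi
C_ON	N_PRO	4	con_on
C_ON	WAT	12	wat_c
S	S	11	s_s
S	PI	9	pi
S	N_PRO	8	s_on
S	WAT	10	wat_on
PI	PI	9	pi
PI	N_PRO	9	pi
PI	WAT	9	pi
N_PRO	N_PRO	13	acc_acc
N_PRO	WAT	10	wat_on
WAT	WAT	10	wat_on
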