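phage	query	query_len	subject	subject_len	query_mismatch	subject_mismatch	ani	snp	indel_bases	start_variation	length_variation	mafft_diffs
1.021	A	43743	B	43743	1	1	0.9999771	0	0	0	0	0
1.021	A	43743	C	43743	2	2	0.9999543	1	0	0	0	0
1.021	B	43743	C	43743	2	2	0.9999543	0	0	0	0	0
1.107	B	10447	C	10447	1	0	0.9999521	0	0	0	0	0
1.107	B	10447	A	10447	3	2	0.9997607	2	0	0	0	2
1.107	C	10447	A	10447	3	2	0.9997607	2	0	0	0	2
1.111	A	40209	B	40209	10	9	0.9997637	0	0	9	0	0
1.115	B	37416	A	37416	2	3	0.9999332	1	0	1	0	0
1.118	B	60458	A	60458	5	5	0.9999173	4	0	0	0	4
1.122	A	44523	B	44523	3	4	0.9999214	2	0	1	0	2
1.139	B	44094	A	43893	6	1	0.9999204	0	201	48	201	201
1.188	A	72305	B	72305	2	3	0.9999654	0	0	2	0	0
1.188	A	72305	C	72305	2	3	0.9999654	0	0	2	0	0
1.188	B	72305	C	72305	1	1	0.9999862	0	0	0	0	0
1.189	B	36855	O	36855	4	3	0.9999050	2	0	1	0	2
1.189	B	36855	C	36855	4	4	0.9998915	3	0	0	0	3
1.189	O	36855	C	36855	2	3	0.9999322	1	0	1	0	1
1.198	B	44343	A	44472	2	43	0.9994933	1	129	0	129	130
1.199	B	48312	A	48312	4	4	0.9999172	3	0	0	0	3
1.211	A	37169	B	37169	1	1	0.9999731	0	0	0	0	0
1.215	B	80834	A	80834	1	2	0.9999814	0	0	1	0	0
1.233	B	36823	A	36823	2	1	0.9999593	0	0	1	0	0
1.237	B	60160	A	60097	64	3	0.9994429	0	63	1	63	64
1.238	A	70467	B	70494	19	20	0.9997233	0	27	19	27	27
1.247	B	43896	A	43896	3	2	0.9999430	1	0	1	0	1
1.249	B	10611	A	10611	1	0	0.9999529	0	0	0	0	0
1.263	B	49640	A	49640	11	12	0.9997683	2	0	9	0	0
1.268	A	59297	B	59297	3	3	0.9999494	2	0	0	0	2
1.270	B	59297	A	59297	3	2	0.9999578	1	0	1	0	1
1.271	B	59297	A	59297	3	3	0.9999494	2	0	0	0	2
1.277	A	59419	B	59297	3	21	0.9997978	1	122	1	122	123
1.283	A	59530	C	59530	3	2	0.9999580	1	0	0	0	1
1.283	A	59530	B	59530	1	1	0.9999832	0	0	0	0	0
1.283	C	59530	B	59530	2	3	0.9999580	1	0	0	0	1
2.095	B	44649	A	44649	3	4	0.9999216	2	0	1	0	2
2.159	A	31617	B	31617	0	0	1.0000000	0	0	0	0	0
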