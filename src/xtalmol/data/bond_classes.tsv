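elem_a	elem_b	order	pi_a	pi_b	mean	sigma	count
C	C	1	*	*	1.530	0.020	1000
C	C	1	1	1	1.410	0.020	500
C	C	2	*	*	1.337	0.015	800
C	C	2	1	1	1.390	0.020	500
C	C	3	*	*	1.203	0.010	100
C	N	1	*	*	1.470	0.020	800
C	N	1	1	1	1.352	0.020	400
C	N	2	*	*	1.280	0.015	400
C	N	2	1	1	1.339	0.015	300
C	N	3	*	*	1.155	0.010	200
C	O	1	*	*	1.426	0.020	900
C	O	1	1	1	1.360	0.020	300
C	O	2	*	*	1.215	0.012	700
N	N	1	*	*	1.425	0.030	200
N	N	2	*	*	1.245	0.020	200
N	N	3	*	*	1.125	0.015	100
N	O	1	*	*	1.400	0.025	200
N	O	2	*	*	1.210	0.015	300
C	S	1	*	*	1.820	0.025	300
C	S	2	*	*	1.670	0.020	100
S	S	1	*	*	2.050	0.030	50
O	S	1	*	*	1.570	0.025	100
O	S	2	*	*	1.440	0.015	200
O	P	1	*	*	1.600	0.025	150
O	P	2	*	*	1.480	0.015	150
C	P	1	*	*	1.840	0.025	100
C	H	1	*	*	1.090	0.020	1000
H	N	1	*	*	1.010	0.020	500
H	O	1	*	*	0.960	0.020	500
O	O	1	*	*	1.470	0.030	50
C	F	1	*	*	1.350	0.015	300
C	Cl	1	*	*	1.790	0.020	300
C	Br	1	*	*	1.950	0.020	150
C	I	1	*	*	2.140	0.025	100
B	F	1	*	*	1.400	0.020	80
B	O	1	*	*	1.370	0.020	80
B	C	1	*	*	1.560	0.025	80
C	Se	1	*	*	1.950	0.030	50
C	Se	2	*	*	1.790	0.025	30
N	S	1	*	*	1.680	0.030	60
N	S	2	*	*	1.550	0.020	40
N	P	1	*	*	1.700	0.030	60
Si	Si	1	*	*	2.340	0.030	40
C	Si	1	*	*	1.870	0.025	80
O	Si	1	*	*	1.630	0.025	80
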