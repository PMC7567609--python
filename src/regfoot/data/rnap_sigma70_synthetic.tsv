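#gauge=wildtype-zero
#units=A.U.
#start=80
#wildtype=TTGACAGTCGCGTCCTATCCTCTTATAATA
pos	val_A	val_C	val_G	val_T
0	3.05925408	2.270818861	2.159245148	0
1	2.860150011	3.195189071	2.606144789	0
2	2.35895987	1.969835422	0	1.949299355
3	0	1.767535656	2.273817874	3.553291979
4	2.923397971	0	2.004218906	1.270012514
5	0	1.791528731	2.54546177	2.608546616
6	0.1283673256	0.364922061	0	0.2696413627
7	0.2460025551	0.03499552455	0.2339059039	0
8	0.1667845993	0	0.1771066309	0.1369110051
9	0.103802666	0.09147706223	0	0.1753436345
10	0.04088404308	0	0.1651633042	0.2888634052
11	0.1187891821	0.1439455873	0	0.1631725897
12	0.5118915597	0.6301816267	0.3236826241	0
13	0.132764391	0	0.08853842982	0.004330157958
14	0.05808663548	0	0.2576155431	0.1111168116
15	0.1970807667	0.2005913103	0.1936554654	0
16	0	0.2586531233	0.1186623936	0.05142153158
17	0.2433787932	0.03393011598	0.3481562897	0
18	0.4509077854	0	0.2239952771	0.09101082502
19	0.03059715544	0	0.2573818797	0.03547669188
20	0.3054848957	0.143815806	0.01146779748	0
21	0.07463203461	0	0.1328125465	0.03919604267
22	0.1707398619	0.1354650218	0.1176038363	0
23	2.025551794	3.276316533	3.274668765	0
24	0	2.595718416	1.952045994	2.380468121
25	2.447533427	2.073883574	2.924607434	0
26	0	1.373561093	2.748409252	2.871302737
27	0	3.959043304	2.969895527	2.029004656
28	3.831770103	2.039841013	2.894369285	0
29	0	0.1529594673	0.1891735089	0.09214724778
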