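probe_id	rsid	chrom	pos	ref	alt	ref_maf
C__SYN0000004_10	rs90000004	1	93104426	A	G	0.0714
C__SYN0000037_10	rs90000037	2	80842828	C	T	0.3071
C__SYN0000021_10	rs90000021	3	40086744	G	A	0.1929
C__SYN0000036_10	rs90000036	4	34636799	T	C	0.3000
C__SYN0000024_10	rs90000024	5	79836768	A	C	0.2143
C__SYN0000016_10	rs90000016	6	42449182	G	T	0.1571
C__SYN0000020_10	rs90000020	7	38215203	A	G	0.1857
C___2171394_10	rs4870723	8	54134548	C	T	0.4200
C__SYN0000027_10	rs90000027	9	58019835	G	A	0.2357
C__SYN0000049_10	rs90000049	10	91591731	T	C	0.3929
C__SYN0000050_10	rs90000050	11	53000604	A	C	0.4000
C__SYN0000039_10	rs90000039	12	88304989	G	T	0.3214
C__SYN0000007_10	rs90000007	13	98497693	A	G	0.0929
C__SYN0000035_10	rs90000035	14	61094097	C	T	0.2929
C__SYN0000032_10	rs90000032	15	10212320	G	A	0.2714
C___2592567_10	rs2271615	16	26805931	T	C	0.4600
C__SYNR000003_10	rs91000003	17	77286796	A	C	0.0050
C___2567433_10	rs10774671	18	81263726	G	T	0.5000
C__SYN0000029_10	rs90000029	19	49459956	A	G	0.2500
C__SYN0000028_10	rs90000028	20	59652361	C	T	0.2429
C__SYN0000044_10	rs90000044	21	62162657	G	A	0.3571
C__SYN0000011_10	rs90000011	22	11364553	T	C	0.1214
C__SYN0000026_10	rs90000026	1	69463390	A	C	0.2286
C__SYN0000009_10	rs90000009	2	35256091	G	T	0.1071
C__SYN0000019_10	rs90000019	3	94549826	A	G	0.1786
C__SYN0000018_10	rs90000018	4	13912050	C	T	0.1714
C__SYN0000003_10	rs90000003	5	20705682	G	A	0.0643
C__SYN0000040_10	rs90000040	6	2082243	T	C	0.3286
C__SYN0000015_10	rs90000015	7	27532968	A	C	0.1500
C__SYN0000047_10	rs90000047	8	6150957	G	T	0.3786
C__SYN0000043_10	rs90000043	9	30105940	A	G	0.3500
C__SYN0000038_10	rs90000038	10	72060471	C	T	0.3143
C__SYN0000017_10	rs90000017	11	50496079	G	A	0.1643
C__SYN0000041_10	rs90000041	12	31510366	T	C	0.3357
C__SYN0000014_10	rs90000014	13	87484720	A	C	0.1429
C__SYN0000005_10	rs90000005	14	72090454	G	T	0.0786
C__SYNR000004_10	rs91000004	15	45325527	A	G	0.0050
C__SYN0000013_10	rs90000013	16	99874375	C	T	0.1357
C__SYNR000001_10	rs91000001	17	54647425	G	A	0.0050
C__SYN0000034_10	rs90000034	18	80303424	T	C	0.2857
C__SYN0000010_10	rs90000010	19	96834503	A	C	0.1143
C__SYNR000002_10	rs91000002	20	11478274	G	T	0.0050
C__SYN0000023_10	rs90000023	21	96845471	A	G	0.2071
C__SYN0000022_10	rs90000022	22	25437899	C	T	0.2000
C___2259382_10	rs2032652	1	87366173	G	A	0.4800
C__SYN0000025_10	rs90000025	2	96413600	T	C	0.2214
C__SYN0000045_10	rs90000045	3	5853751	A	C	0.3643
C__SYN0000033_10	rs90000033	4	79280315	G	T	0.2786
C__SYN0000006_10	rs90000006	5	16395035	A	G	0.0857
C__29554891_10	rs9786184	6	18865074	C	T	0.4500
C__SYNR000005_10	rs91000005	7	53183792	G	A	0.0050
C__SYN0000001_10	rs90000001	8	19140476	T	C	0.0500
C__SYN0000048_10	rs90000048	9	76374881	A	C	0.3857
C__SYN0000002_10	rs90000002	10	48094943	G	T	0.0571
C__SYN0000042_10	rs90000042	11	96874932	A	G	0.3429
C__SYN0000030_10	rs90000030	12	42362410	C	T	0.2571
C__SYN0000046_10	rs90000046	13	67559241	G	A	0.3714
C__SYN0000008_10	rs90000008	14	4146467	T	C	0.1000
C__SYN0000031_10	rs90000031	15	71908839	A	C	0.2643
C__SYN0000012_10	rs90000012	16	94684198	G	T	0.1286
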