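# synthetic rCRS gene map (canonical NC_012920.1 coordinates, overlaps trimmed)
#length=16569
# start	end	label	class	strand
577	647	MTTF	tRNA	+
648	1601	MTRNR1	rRNA	+
1602	1670	MTTV	tRNA	+
1671	3229	MTRNR2	rRNA	+
3230	3304	MTTL1	tRNA	+
3307	4262	MTND1	protein-coding	+
4263	4331	MTTI	tRNA	+
4332	4400	MTTQ	tRNA	-
4402	4469	MTTM	tRNA	+
4470	5511	MTND2	protein-coding	+
5512	5579	MTTW	tRNA	+
5587	5655	MTTA	tRNA	-
5657	5729	MTTN	tRNA	-
5761	5826	MTTC	tRNA	-
5827	5891	MTTY	tRNA	-
5904	7445	MTCO1	protein-coding	+
7446	7514	MTTS1	tRNA	-
7518	7585	MTTD	tRNA	+
7586	8269	MTCO2	protein-coding	+
8295	8364	MTTK	tRNA	+
8366	8526	MTATP8	protein-coding	+
8527	9206	MTATP6	protein-coding	+
9207	9990	MTCO3	protein-coding	+
9991	10058	MTTG	tRNA	+
10059	10404	MTND3	protein-coding	+
10405	10469	MTTR	tRNA	+
10470	10759	MTND4L	protein-coding	+
10760	12137	MTND4	protein-coding	+
12138	12206	MTTH	tRNA	+
12207	12265	MTTS2	tRNA	+
12266	12336	MTTL2	tRNA	+
12337	14148	MTND5	protein-coding	+
14149	14673	MTND6	protein-coding	-
14674	14742	MTTE	tRNA	-
14747	15887	MTCYB	protein-coding	+
15888	15953	MTTT	tRNA	+
15956	16023	MTTP	tRNA	-
16024	576	CR	control	+
16184	16193	polyC	special	+
5721	5798	OriL	special	+
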