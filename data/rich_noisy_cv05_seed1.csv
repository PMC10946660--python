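time_h,od660,lum
0.0,0.03,1812.2402414583635
0.25,0.039403411764868196,1969.8037376400364
0.5,0.05175480387892676,1879.3729762073747
0.75,0.0679778016490254,1693.6144022498788
1.0,0.08928593529438886,1849.2777511125835
1.25,0.11727307432730792,1767.3330131932144
1.5,0.15403261445529504,1645.463277638369
1.75,0.2023139793596126,1701.857490329613
2.0,0.26572815977586833,1647.073649244526
2.25,0.34901753989775175,1606.5477233424094
2.5,0.4584102189072415,1553.282199913362
2.75,0.602085077445108,1564.6348622983862
3.0,0.7907822070501465,1445.6452812889759
3.25,1.0386038749441284,1477.0876209643268
3.5,1.3640652363225325,1471.4840009158281
3.75,1.7914720466972842,1662.8179959739823
4.0,2.3527262215900158,1962.4487581182805
4.25,3.08969042650826,2483.657449204569
4.5,4.057281910079447,3014.9518412242064
4.75,5.3275155239477,3703.5040718628907
5.0,6.994778465118294,4360.098969189394
5.25,9.18269745724368,4885.459330686823
5.5,12.053052699620448,5905.17658004948
5.75,15.817305718872952,6419.873731392613
6.0,20.75142803520125,5817.806413115141
6.25,27.214845609738397,6557.331059750727
6.5,35.67440437623927,7671.649820821024
6.75,46.73428574778185,8087.170027381596
7.0,61.17263188811254,8862.752541706963
7.25,79.98513012962312,9367.502159646998
7.5,104.43462747254908,10841.575740216693
7.75,136.10351168826958,9675.650828046542
8.0,176.94134677547092,10493.539760815884
8.25,229.29288069349442,12345.786403439195
8.5,295.8797001176686,11972.435453841323
8.75,379.69099865113236,12430.486838140341
9.0,483.715473976081,12133.09744774675
9.25,610.4227295115077,11845.049141986883
9.5,760.8979063932278,13375.743532601256
9.75,933.5938320436998,13730.262765777234
10.0,1122.8735161061143,13200.086812288288
10.25,1317.9521921429593,13916.978009878425
10.5,1503.3955210509932,14695.09237165606
10.75,1662.3310694113388,14376.455345635126
11.0,1781.955787104169,15280.786586265216
11.25,1858.2657397987923,15642.191170378106
11.5,1896.6367335821005,15623.666544253629
11.75,1908.8292375430274,14362.627652524054
12.0,1910.0679431718036,5468.91060675033
12.25,1910.0980367905297,131.78752859052184
12.5,1910.0988935569715,1.8497518873087269
12.75,1910.0989072760606,0.0248412987210192
13.0,1910.0989074758093,0.0003811944549498509
13.25,1910.0989074787121,4.953573334300362e-06
13.5,1910.0989074787533,6.451683087900462e-08
13.75,1910.0989074787537,0.0
14.0,1910.0989074787542,0.0
14.25,1910.0989074787547,0.0
14.5,1910.0989074787547,0.0
14.75,1910.0989074787547,0.0
15.0,1910.0989074787547,0.0
15.25,1910.0989074787547,0.0
15.5,1910.0989074787547,0.0
15.75,1910.0989074787547,0.0
16.0,1910.0989074787547,0.0
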