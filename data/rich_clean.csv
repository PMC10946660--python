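time_h,od660,lum
0.0,0.03,1783.43949044586
0.25,0.039403411764868196,1892.9322578918748
0.5,0.05175480387892676,1850.905717670315
0.75,0.0679778016490254,1809.8257642499996
1.0,0.08928593529438886,1769.689414131624
1.25,0.11727307432730792,1730.5084721871856
1.5,0.15403261445529504,1692.321605127255
1.75,0.2023139793596126,1655.2150934489218
2.0,0.26572815977586833,1619.3605760428416
2.25,0.34901753989775175,1585.0858977426722
2.5,0.4584102189072415,1553.0153922912586
2.75,0.602085077445108,1524.3717140750264
3.0,0.7907822070501465,1501.7092279732478
3.25,1.0386038749441284,1491.0210874476431
3.5,1.3640652363225325,1509.2468866836307
3.75,1.7914720466972842,1615.8135389738907
4.0,2.3527262215900158,1961.0040925510639
4.25,3.08969042650826,2523.3677104847807
4.5,4.057281910079447,3138.996988892102
4.75,5.3275155239477,3756.0934591801724
5.0,6.994778465118294,4363.769908319965
5.25,9.18269745724368,4959.392702809314
5.5,12.053052699620448,5542.329982970846
5.75,15.817305718872952,6112.538121570023
6.0,20.75142803520125,6670.169290509303
6.25,27.214845609738397,7215.444658526864
6.5,35.67440437623927,7748.608533681941
6.75,46.73428574778185,8269.910144450347
7.0,61.17263188811254,8779.595575171317
7.25,79.98513012962312,9277.90352396363
7.5,104.43462747254908,9765.062300347148
7.75,136.10351168826958,10241.286845958131
8.0,176.94134677547092,10706.774941372438
8.25,229.29288069349442,11161.701762280294
8.5,295.8797001176686,11606.211564070669
8.75,379.69099865113236,12040.404496092115
9.0,483.715473976081,12464.315009606964
9.25,610.4227295115077,12877.875382236916
9.5,760.8979063932278,13280.852171710869
9.75,933.5938320436998,13672.732150444988
10.0,1122.8735161061143,14052.511667464403
10.25,1317.9521921429593,14418.296431109145
10.5,1503.3955210509932,14766.512697748596
10.75,1662.3310694113388,15090.242768231961
11.0,1781.955787104169,15375.189399434626
11.25,1858.2657397987923,15587.184874474218
11.5,1896.6367335821005,15615.391924100117
11.75,1908.8292375430274,14749.02168033821
12.0,1910.0679431718036,5315.669695213892
12.25,1910.0980367905297,126.2051676732003
12.5,1910.0988935569715,1.8226063788807756
12.75,1910.0989072760606,0.025910335819641493
13.0,1910.0989074758093,0.0003679688487708678
13.25,1910.0989074787121,5.08560497081961e-06
13.5,1910.0989074787533,6.182105359060875e-08
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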