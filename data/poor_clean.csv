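time_h,od660,lum
0.0,0.5,29.723991507431002
0.25,0.5997054509669334,31.85166232657452
0.5,0.7192906257417979,31.517253443878325
0.75,0.8627083660884091,31.236127405566783
1.0,1.0347024342102888,31.066496152358987
1.25,1.2409582161568593,31.13907672483972
1.5,1.488288497214901,31.82882504121743
1.75,1.7848553832443164,34.445542751826544
2.0,2.1404351869334164,41.41932396231045
2.25,2.5667342787852037,51.38624388071508
2.5,3.0777652508644002,62.06467739414291
2.75,3.690294251560945,72.83589851992066
3.0,4.424372029696766,83.55539069033274
3.25,5.303962849824645,94.18148758760161
3.5,6.357687688713547,104.70023381061655
3.75,7.619699166886396,115.10673797237955
4.0,9.130707774489899,125.39951545794595
4.25,10.939179695752227,135.5784931231767
4.5,13.102725263583588,145.64422118598821
4.75,15.689698906947944,155.59753296322987
5.0,18.781020108012996,165.43938611403826
5.25,22.472223816927478,175.17078295199323
5.5,26.87572776284832,184.79272661218909
5.75,32.123284590047724,194.3061938607958
6.0,38.36854765050402,203.71211537172425
6.25,45.78963042822268,213.01135813765984
6.5,54.59145668934556,222.20470797762331
6.75,65.00760695319208,231.29284926133164
7.0,77.30121716812313,240.27634042091248
7.25,91.76431325098241,249.1555834097803
7.5,108.71475037284911,257.93078439044524
7.75,128.48968069861422,266.60190273182775
8.0,151.43423639922904,275.1685840912118
8.25,177.88392114875134,283.63007135393576
8.5,208.13923124749059,291.9850855029611
8.75,242.43130545700768,300.23166431775445
9.0,280.87831639007635,308.3669423512896
9.25,323.4339922049439,316.38684711879455
9.5,369.83235457458875,324.2856767555883
9.75,419.53639504681104,332.0555045524281
10.0,471.7024207125003,339.68532853921806
10.25,525.1749023242209,347.15983373327254
10.5,578.526388996274,354.4575441563566
10.75,630.1515000215641,361.5479651927131
11.0,678.4116756772983,368.38695122082987
11.25,721.8108113717836,374.90872776724257
11.5,759.1674373316192,381.01108821380734
11.75,789.7449490570077,386.5253247435961
12.0,813.3125856083344,391.1478779898873
12.25,830.1333753324034,394.260148871976
12.5,840.9028264834199,394.3428380659268
12.75,846.6884990699727,386.369449189363
13.0,848.9455878096562,344.50646244553116
13.25,849.4794608635005,177.57642784920301
13.5,849.5738096135492,37.05355766365202
13.75,849.5925947771203,5.505795834978758
14.0,849.5963457788198,0.7150890497881349
14.25,849.596899955969,0.08872150418005559
14.5,849.5969708850128,0.010923019602614535
14.75,849.5969797390107,0.001343434921862538
15.0,849.5969808406193,0.000165217756921438
15.25,849.5969809776367,2.0313560668924357e-05
15.5,849.5969809946555,2.516004421451285e-06
15.75,849.5969809967959,3.025400918873261e-07
16.0,849.596980997057,3.567465723621071e-08
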