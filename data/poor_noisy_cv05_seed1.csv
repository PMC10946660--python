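time_h,od660,lum
0.0,0.5,30.20400402430606
0.25,0.5997054509669334,33.14514993305093
0.5,0.7192906257417979,32.00199439723937
0.75,0.8627083660884091,29.2304133854028
1.0,1.0347024342102888,32.46365135080655
1.25,1.2409582161568593,31.80170405442132
1.5,1.488288497214901,30.94752357768404
1.75,1.7848553832443164,35.41618558982402
2.0,2.1404351869334164,42.128157296845956
2.25,2.5667342787852037,52.08200592488192
2.5,3.0777652508644002,62.075340088842744
2.75,3.690294251560945,74.75970919615631
3.0,4.424372029696766,80.4359818982801
3.25,5.303962849824645,93.30136951838162
3.5,6.357687688713547,102.08052791349826
3.75,7.619699166886396,118.45522440657507
4.0,9.130707774489899,125.4918968878552
4.25,10.939179695752227,133.4448931077971
4.5,13.102725263583588,139.8887333700002
4.75,15.689698906947944,153.41899853229938
5.0,18.781020108012996,165.30021335081216
5.25,22.472223816927478,172.5593812225755
5.5,26.87572776284832,196.89078144150002
5.75,32.123284590047724,204.07582006104525
6.0,38.36854765050402,177.6802955998701
6.25,45.78963042822268,193.58280201693577
6.5,54.59145668934556,219.9977842127615
6.75,65.00760695319208,226.18197361541615
7.0,77.30121716812313,242.55214588696316
7.25,91.76431325098241,251.5617304761676
7.5,108.71475037284911,286.3654166961231
7.75,128.48968069861422,251.87722595076494
8.0,151.43423639922904,269.6883509646659
8.25,177.88392114875134,313.7188533706654
8.5,208.13923124749059,301.1984203777915
8.75,242.43130545700768,309.958502881369
9.0,280.87831639007635,300.1726254774653
9.25,323.4339922049439,291.0121150240113
9.5,369.83235457458875,326.6026899100713
9.75,419.53639504681104,333.4526911052809
10.0,471.7024207125003,319.08002865849284
10.25,525.1749023242209,335.08922465726704
10.5,578.526388996274,352.74316013707045
10.75,630.1515000215641,344.44629266274404
11.0,678.4116756772983,366.1250757000361
11.25,721.8108113717836,376.2317595130382
11.5,759.1674373316192,381.2129865743845
11.75,789.7449490570077,376.39915635651244
12.0,813.3125856083344,402.4239468213804
12.25,830.1333753324034,411.6992322858928
12.5,840.9028264834199,400.2160957030444
12.75,846.6884990699727,370.4281940148709
13.0,848.9455878096562,356.88877908358006
13.25,849.4794608635005,172.96621795073463
13.5,849.5738096135492,38.669320149122086
13.75,849.5925947771203,5.212173580435213
14.0,849.5963457788198,0.7475890747326271
14.25,849.596899955969,0.08852201785936929
14.5,849.5969708850128,0.010249465301427637
14.75,849.5969797390107,0.001320877239237714
15.0,849.5969808406193,0.0001654583213167287
15.25,849.5969809776367,2.056665942071406e-05
15.5,849.5969809946555,2.3925144922864903e-06
15.75,849.5969809967959,2.8589690391781375e-07
16.0,849.596980997057,3.598726454829713e-08
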