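peak,rt_min,name,compound_class,formula,reference_substance,adduct,measured_mz,theoretical_mz,ppm_printed,ppm_consistent,cascade,msms
1,15.330,Gardenoside,iridoid,C16H22O10,0,[M+Cl]-,409.0910,409.0907,0.7,1,,193.0510;373.1151;167.0721;149.0610;89.0316;211.0601;161.0742;179.0558;123.0463;409.0873;143.0383
2,17.542,Shanzhiside,iridoid,C16H24O11,1,[M-H]-,391.1249,391.1246,0.8,1,glucose;CO2;H2O,391.1272;185.0840;167.0716;229.0746;119.0328;89.0251;211.0643;149.0615;179.0578;123.0711
2,17.542,Shanzhiside,iridoid,C16H24O11,1,[M+Cl]-,427.1017,427.1013,1.0,1,,391.1273;89.0261;167.0721;185.0825;229.0728
3,18.098,Geniposidic acid,iridoid,C16H22O10,1,[M+Cl]-,409.0911,409.0907,1.0,1,HCl;glucose,373.1163;149.0619;211.0617;167.0718;123.0466;119.0355;409.0875;89.0252;193.0534
4,19.248,DAAME,iridoid,C17H24O11,1,[M+Cl]-,439.1023,439.1013,2.4,1,HCl;glucose,439.1033;241.0684;101.0240
5,21.181,Gardenoside,iridoid,C17H24O11,1,[M+Cl]-,439.1023,439.1013,2.4,1,HCl;glucose,439.1088;241.0733;403.1295
6,21.668,Jasminoside D,monocyclic monoterpenoid,C16H26O8,0,[M-H]-,345.1562,345.1555,2.1,1,,165.0915;89.0249;119.0343;101.0267
6,21.668,Jasminoside D,monocyclic monoterpenoid,C16H26O8,0,[M+Cl]-,381.1333,381.1322,3.0,1,,165.0935;345.1577;89.0264;179.0570;119.0368;101.0260;121.1039
7,22.668,Ixoroside,iridoid,C16H24O9,0,[M+Cl]-,395.1114,395.1114,-0.1,1,,359.1353;197.0822
8,23.743,SME,iridoid,C17H24O11,1,[M+Cl]-,439.1025,439.1013,2.8,1,HCl;glucose,439.1056;403.1332;241.0704
9,26.666,Jasminoside B,monocyclic monoterpenoid,C16H26O8,1,[M+Cl]-,381.1332,381.1322,2.7,1,HCl,381.1332
10,30.424,Chlorogenic acid,organic acid,C16H18O9,1,[M+Cl]-,389.0648,389.0645,0.5,0,HCl;caffeoyl,191.0564;353.0885
11,31.971,Genipin gentiobioside,iridoid,C23H34O15,1,[M+Cl]-,585.1619,585.1592,4.7,1,HCl;gentiobiose,585.1644;225.0778;549.1867;123.0462;101.0257;207.0671
12,36.838,Geniposide,iridoid,C17H24O10,1,[M+Cl]-,423.1076,423.1063,3.0,1,HCl;glucose,423.1095;225.0760;387.1288
13,42.163,Jasminoside A,monocyclic monoterpenoid,C16H26O7,0,[M+Cl]-,365.1387,365.1373,4.0,1,,365.1405
14,43.103,Jasminoside E,monocyclic monoterpenoid,C16H26O7,0,[M+Cl]-,365.1386,365.1373,3.7,1,,365.1385
15,53.572,Rutin,flavonoid,C27H30O16,1,[M-H]-,609.1482,609.1461,3.4,1,rutinosyl,609.1525;301.0359
15,53.572,Rutin,flavonoid,C27H30O16,1,[M+Cl]-,645.1250,645.1228,3.4,1,,609.1501;301.0366
16,55.917,6'-Trans-sinapoyl shanzhiside,iridoid,C27H34O15,0,[M-H]-,597.1855,597.1825,5.0,1,sinapoyl;glucose;CO2;H2O,597.1923;391.1285;223.0633;185.0825;205.0521;167.0717;229.0734
16,55.917,6'-Trans-sinapoyl shanzhiside,iridoid,C27H34O15,0,[M+Cl]-,633.1619,633.1592,4.3,1,,597.1881;391.1260;205.0511
17,56.908,6'-Trans-sinapoyl gardoside,iridoid,C27H32O14,0,[M+Cl]-,615.1511,615.1486,4.1,1,,579.1770;325.0927;367.1043;223.0612;385.1151;193.0505;205.0506;123.0451
18,59.556,"3,4-Dicaffeoylquinic acid",organic acid,C25H24O12,0,[M-H]-,515.1215,515.1195,3.9,1,,353.0910;191.0579;515.1277;179.0348;173.0443;161.0227;135.04738;155.0361
19,61.039,"6''-O-Trans-coumaroyl genipin gentiobioside",iridoid,C32H40O17,0,[M-H]-,695.2208,695.2193,2.2,1,,695.2261;469.1387;163.0391;145.0249;123.0456;367.1069;225.0764;663.2029;101.0252
20,61.814,Crocin I,crocin,C44H64O24,1,[M+Cl]-,1011.3519,1011.3482,3.7,1,HCl;gentiobiose;gentiobiose,1011.3585;651.2726;327.1621;975.3809;283.1722
21,63.359,"3,4-Di-O-caffeoyl-5-O-(3-hydroxy-3-methylglutaroyl) quinic acid",organic acid,C31H32O16,0,[M-H]-,659.1647,659.1618,4.5,1,,497.1325;659.1672;335.0767;191.0555;353.0892;161.0458
22,63.534,6'-O-Trans-sinapoyl jasminoside L,monocyclic monoterpenoid,C27H36O12,0,[M+Cl]-,587.1926,587.1901,4.3,1,,521.2075;533.2077;551.2697;551.2697;205.0517;367.1050;223.0621;587.1956;165.0928;179.0727;385.1160
23,64.290,Jasminoside T,monocyclic monoterpenoid,C21H34O11,0,[M+Cl]-,497.1810,497.1795,3.0,1,,497.1855;461.2069;167.1092;329.0637;293.0889
24,64.985,6'-O-Trans-sinapoyl geniposide,iridoid,C28H34O14,0,[M-H]-,593.1895,593.1876,3.2,1,,593.1943;205.0518;223.0649;225.0781;367.1057;207.0645;123.0466;101.0236
24,64.985,6'-O-Trans-sinapoyl geniposide,iridoid,C28H34O14,0,[M+Cl]-,629.1668,629.1643,4.0,1,,593.1936;205.0511;225.0773;223.0627;123.0457
25,65.278,Crocin II,crocin,C38H54O19,1,[M+Cl]-,849.2978,849.2953,2.9,1,HCl;gentiobiose;glucose,327.1615;283.1723;651.2701;239.1815;849.3028;489.2166
26,71.292,6'-O-Trans-sinapoyl jasminoside A,monocyclic monoterpenoid,C27H36O11,0,[M+Cl]-,571.1957,571.1952,0.9,1,,535.2258;325.0947;265.0740;223.0627;205.0521;385.1184;221.0848
27,75.160,13-cis-Crocin II,crocin,C44H64O24,0,[M+Cl]-,1011.3509,1011.3482,2.7,1,,1011.3556;651.2711;327.1611;975.3767
28,75.958,Crocin II,crocin,C32H44O14,0,[M+Cl]-,687.2437,687.2425,1.7,1,,327.1608;651.2707;283.1704;687.2467;239.1814;323.0971;179.0566
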