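analyte,peak,slope,intercept,r_squared,range_min_ng,range_max_ng,lod_ng,loq_ng,channel_nm
Shanzhiside,2,410245,-1479,0.9998,25.78,1030,2.06,7.73,254
Geniposidic acid,3,664663,-107,0.9997,6,240,1.8,5.3,254
DAAME,4,604893,-2756,0.9999,8.806,352.24,1.76,7.04,254
Gardenoside,5,505562,-3934,0.9999,16.848,673.92,1.68,6.74,254
SME,8,615010,-1709,1.0000,7.196,287.84,2.16,7.2,254
Jasminoside B,9,989612,-7323,0.9995,12.1,484,2.42,6.05,254
Chlorogenic acid,10,2746452,-3099,0.9999,3.0768,123.072,0.92,3.69,324
Genipin gentiobioside,11,460657,-29122,0.9999,187.75,7510,3.76,13.14,254
Geniposide,12,746351,-82879,0.9999,380.6,15224,2.44,12.18,254
Rutin,15,1071542,-3095,0.9998,6.57,262.6,1.97,5.91,254
Crocin I,20,4453568,-29472,0.9999,20.25,810,0.61,2.03,430
Crocin II,25,4595808,-23116,0.9999,15,600,0.45,1.5,430
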