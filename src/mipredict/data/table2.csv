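ID,Hand,EXP,SLP,COFF,ALC,CIG,CALM,INT,CONCENT,BODY,MENTAL,NSLP,preAP,ES,AP,ACC,ACCSTD
sbj1,R,,4,5,0,0,5,4,3,3,3,0.4,80,3.8,88,96.11,2.60
sbj2,R,,3,0,0,0,4,3.8,3.8,3.4,3.4,0.3,50,4.4,74,95.65,4.46
sbj3,R,Yes,3,0,0,0,4.2,3.6,3.6,3.8,3.4,0,70,3.4,71,84.60,5.33
sbj4,R,,2,20,15,0,4.2,3.6,3.6,4,4,0,70,4,75,83.07,4.46
sbj5,R,,4,0,0,0,4,4,4.2,3.6,3.2,0.8,80,4.6,85,81.97,4.66
sbj6,R,,3,0,22,0,3,2.6,3.6,2.8,3.4,0,65,3,68,79.65,4.47
sbj7,R,,1,2,0,1,5,3.6,2.8,1,2,0.4,50,2.8,72,79.18,8.15
sbj8,R,,1,2,0,1,4,3,3.6,4,3,2.4,75,3.6,69,78.96,6.94
sbj9,R,,2,30,16,16,5,4.4,4,2,4,0,60,1.6,56.2,78.89,6.53
sbj10,R,,3,0,0,0,4,2,2,3,3,0.7,70,2.4,64,78.72,6.73
sbj11,R,,3,17,0,0,2.8,4.4,2.8,3.4,3.8,0,80,3,65,76.90,5.05
sbj12,R,,3,16,0,0,4,4,4.4,4.8,4.4,0,80,4.2,70.6,76.00,8.20
sbj13,R,,3,0,0,0,5,4.2,4.4,4.4,4.4,0.2,75,4.2,72,75.33,8.85
sbj14,R,,1,23,0,0,4.2,1.8,4.4,3,3,0,80,3.2,65.6,75.19,5.03
sbj15,R,,5,0,17.5,0,4,2.4,3.4,4,3.8,3.2,60,4,63.8,74.24,5.61
sbj16,R,,4,22,0,0,2.4,2.2,2.2,3,2.8,1,60,3,62,73.64,6.05
sbj17,R,,4,1,0,0,4.4,4.8,4.2,5,4.6,0.4,80,4,75,72.54,6.49
sbj18,R,,2,12,0,0,3,4,3.6,3.2,4,0.6,80,3.8,72,71.44,6.10
sbj19,R,,3,0,14,14,4,2,3,4,4,0,70,4,66,71.44,6.43
sbj20,R,,2,0,0,0,4.8,3.6,3,3,3.4,0.4,50,2.4,58,70.99,5.50
sbj21,B,,4,7,0,0,3,3,3,3,3,0,70,2.4,56,69.33,6.85
sbj22,R,Yes,4,0,0,0,5,4,5,5,5,0.4,90,5,86,68.33,6.30
sbj23,R,,3,0,0,0,3.8,3.4,3.6,4,4,0.8,75,2.6,59,66.47,6.30
sbj24,R,,4,4,0,0,5,3.6,3.6,4,4.2,0.4,75,4.2,65,66.42,6.38
sbj25,R,,2,7,0,0,3.8,2.6,2.6,3.2,3.2,0,70,3.2,56,64.50,5.96
sbj26,R,,3,0,8,0,3.8,3.2,3.2,3.2,3.2,1.2,80,3.8,60,63.63,6.27
sbj27,R,,3,2,0,0,3,3,3,3,3,1.3,60,3,61,63.22,5.84
sbj28,R,,2,0,0,0,4.2,2.8,3,4,3.8,0.6,90,2.6,52,63.14,6.27
sbj29,R,,2,0,0,0,5,2.6,4,5,5,0,50,2,61,63.04,6.98
sbj30,R,,4,0,0,0,4.6,3.2,4.2,4.2,4.4,0,60,4,58,62.96,5.97
sbj31,R,,2,5,0,0,3,3,3,3,3,0,50,2,50,62.43,5.26
sbj32,R,,3,0,0,2,4,4.2,3.4,3.8,4.2,0,65,3.4,61,61.17,5.19
sbj33,R,,4,0,0,0,3.2,2.6,2.8,2.8,3,0,70,2.2,62,61.13,5.15
sbj34,R,,2,0,0,0,5,4.8,3.4,5,5,0,75,3.2,60,60.83,5.28
sbj35,R,,3,0,0,0,3.8,3.6,3.6,5,5,0,65,4,58,60.35,5.95
sbj36,R,Yes,3,0,0,0,3,2.8,2.4,2.4,2.8,1,60,2.2,61.25,60.18,4.87
sbj37,R,,4,12,0,0,3.6,4.2,3.8,3.4,3.6,0,70,4,59,59.71,6.69
sbj38,R,,2,0,0,0,3.8,3.4,2.2,3,2.8,0,70,1.6,52,59.19,5.31
sbj39,R,,4,0,0,0,4,3,2.6,2.8,2.6,0.6,75,2.8,61,58.07,6.42
sbj40,R,,5,0,0,0,4.4,3.6,4,4,4,0,81,2,50.4,57.69,5.54
sbj41,R,,5,0,0,0,3,2.6,2.2,4.8,4.8,0,80,1.8,52,57.64,5.71
sbj42,R,Yes,3,0,0,0,4,4,3.2,3.8,3.6,0.4,80,3,62,57.29,6.54
sbj43,R,,2,0,23,0,3.8,3.2,3.2,4,4,0.6,70,2.8,59,56.76,5.37
sbj44,R,,1,2,0,0,3,3,2.6,3,2.6,0.3,60,2.8,56,56.68,5.54
sbj45,B,,2,4,0,0,3,3,3,3,3,0.2,70,3,64.2,55.81,5.53
sbj46,R,Yes,3,0,0,0,4.8,4.8,4,4,4,0,80,3.6,58,55.40,6.01
sbj47,R,Yes,5,0,0,0,3.4,1.2,1.8,2.6,2.6,0,80,2.6,64,54.57,5.01
sbj48,R,,4,0,0,0,3.4,2.4,2.8,3.2,2.6,4.8,83,4.8,66,54.11,6.48
sbj49,R,,1,11,0,0,3.8,4,3.2,2.8,2,0,80,3.4,62,53.16,5.31
sbj50,R,,4,6,0,0,4,4,3.6,3.6,3.6,0,70,2.6,58,52.58,6.11
sbj51,R,,4,0,0,0,4,4,2.8,3.8,3.8,0.8,0,2.4,55,52.14,5.46
sbj52,R,,2,0,0,0,3.4,3.4,3.4,3.2,3.4,1,70,3,66.25,47.90,6.03
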