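x,y1,y2,y3
1.32186814567,0.156740078672,0.460188648533,0.383071272795
0.316635319256,0.137483278165,0.132382286845,0.73013443499
1.57579375973,0.0257930045436,0.356162987802,0.618044007654
1.09210408718,0.338357417696,0.49946094998,0.162181632323
-0.717467956337,0.657412139331,0.0837435289933,0.258844331676
1.92686705491,0.0131927921099,0.927816672533,0.0589905353567
1.28341910597,0.183684796501,0.687448176319,0.12886702718
1.35819291583,0.298550727833,0.577386893921,0.124062378246
-0.615659101973,0.623010900042,0.100386738036,0.276602361921
0.351157813687,0.270117573256,0.432259760248,0.297622666496
0.112394072698,0.0438031642246,0.0305561150793,0.925640720696
1.78029496655,0.0518424529433,0.263918493564,0.684239053493
0.931595360242,0.680253515546,0.257982469381,0.0617640150736
1.46828483981,0.571317114717,0.308339701181,0.120343184102
0.330242596482,0.480550960467,0.2534350706,0.266013968933
-0.318283834646,0.44830432086,0.102916555618,0.448779123523
0.663754361048,0.697767178683,0.205427274479,0.0968055468382
-0.808548231687,0.52657145417,0.0556836785574,0.417744867273
1.48289351598,0.40271670425,0.44500386083,0.15227943492
0.894993197366,0.0746362219546,0.701284362593,0.224079415453
1.27426322026,0.0742151747118,0.328488450497,0.597296374791
0.0635779043896,0.600848410281,0.042287726338,0.356863863381
1.91209407318,0.339992359641,0.581784863136,0.078222777223
1.67936336397,0.482169687267,0.410872703474,0.106957609259
1.33515049122,0.0021045321886,0.0957960977575,0.902099370054
-0.416083876444,0.308214441061,0.383640330614,0.308145228325
0.400163011181,0.474301285322,0.0502668241091,0.475431890569
-0.868588702638,0.759434313815,0.0463622604476,0.194203425738
-0.537131523797,0.567799525325,0.177721040768,0.254479433907
1.04914685973,0.0645567364846,0.461861087176,0.473582176339
1.23428646772,0.724811772791,0.0653464781381,0.209841749071
1.9025291973,0.400934623517,0.377759381457,0.221305995026
-0.0225239255855,0.681858683729,0.0901799290189,0.227961387252
0.111379118105,0.186301789344,0.465263923961,0.348434286695
0.408667433827,0.728256501672,0.257063024507,0.0146804738219
-0.431585922747,0.554037348274,0.212002551147,0.233960100579
-0.610235483994,0.586547753819,0.0264435548949,0.387008691287
0.427114778678,0.677880438934,0.046815099131,0.275304461935
-0.319271952847,0.601738254133,0.111479135658,0.286782610209
1.00944198405,0.0986489717673,0.236578428177,0.664772600055
0.311455756617,0.169536043827,0.000508407500241,0.829955548672
1.49803458817,0.0140370980799,0.580255639233,0.405707262687
1.10079530601,0.13260094164,0.407428217632,0.459970840728
-0.0629000758539,0.401033146555,0.0252583685252,0.57370848492
1.49677940419,0.006168507981,0.340312328269,0.65351916375
1.41429307249,0.671350610847,0.107458728062,0.221190661091
0.162435137091,0.286692311153,0.355951724378,0.357355964468
-0.135015688209,0.794448192986,0.190652781642,0.0148990253718
1.04748651192,0.132117265406,0.482762709,0.385120025594
-0.580742549172,0.871006605111,3.34778549816e-05,0.128959917034
-0.400275392575,0.763720939218,0.134214013036,0.102065047745
-0.977913190747,0.934180334117,1.91712995351e-05,0.0658004945839
1.36077313251,0.143297951001,0.796023915498,0.0606781335011
0.994552569776,0.285994962133,0.469784994445,0.244220043422
1.11549613588,0.521598173295,0.116199952511,0.362201874194
1.34218709307,0.226324900623,0.0870182509367,0.686656848441
0.376747326615,0.664559839248,0.190703688766,0.144736471986
0.706223587859,0.275924284588,0.0754391704283,0.648636544984
-0.580609005617,0.194288264383,0.185087403225,0.620624332392
-0.656409779392,0.87006624238,0.0703142895839,0.0596194680358
1.00520888537,0.417463448819,0.276084083372,0.306452467809
0.413288618429,0.286718601259,0.466122507902,0.247158890839
0.695708319444,0.207664726245,0.732472626847,0.0598626469082
1.29499657225,0.557926866526,0.0561452597609,0.385927873713
0.904154960002,0.520880803819,0.201741972046,0.277377224134
0.660738201974,0.0570836362685,0.516277866127,0.426638497604
0.677621482236,0.52366593797,0.352748206152,0.123585855878
-0.0881497058122,0.0377344990598,0.356983719192,0.605281781748
-0.907546496296,0.631970230092,0.000773407465463,0.367256362442
0.310152167697,0.3086890743,0.421235320204,0.270075605496
-0.356245981541,0.478614306513,0.157524795846,0.363860897642
0.225585931174,0.0262788812977,0.0962604705986,0.877460648104
1.5602092198,0.0422409809922,0.746567924708,0.2111910943
-0.298181542404,0.944427961747,1.60635607907e-06,0.0555704318966
-0.825091774933,0.940718030289,0.0166791711601,0.0426027985507
-0.155848323934,0.816945424721,7.6010485092e-05,0.182978564794
-0.1192187267,0.517934759808,0.00955077902679,0.472514461165
0.985749544181,0.238433844272,0.160899433586,0.600666722142
0.671096457024,0.275230249643,0.380384488264,0.344385262093
1.35169462732,0.0264835318354,0.78083801199,0.192678456174
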