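SUBJECT_ID,VENTRICLES,HIPPOCAMPUS,WHOLEBRAIN,ENTORHINAL,FUSIFORM,MIDTEMP,ICV,FDG,PIB,AV45,RAVLT_IMMEDIATE,RAVLT_LEARNING,RAVLT_FORGETTING,RAVLT_PERC_FORGETTING,FAQ,ECOG_PT_MEM,ECOG_PT_LANG,ECOG_PT_VISSPAT,ECOG_PT_PLAN,ECOG_PT_ORGAN,ECOG_PT_DIVATT,ECOG_PT_TOTAL,ECOG_SP_MEM,ECOG_SP_LANG,ECOG_SP_VISSPAT,ECOG_SP_PLAN,ECOG_SP_ORGAN,ECOG_SP_DIVATT,ECOG_SP_TOTAL,ABETA,PTAU,TAU,AGE,PTGENDER,PTEDUCAT,APOE4,MMSE_M0,MMSE_M6,MMSE_M12,MMSE_M24,LABEL_24M,ADAS11,ADAS13,MOCA,CDR,CDRSB
SYN00000,-1.255,-0.5952,0.7109,0.265,1.015,-0.8695,1.1505,0.6743,-0.0532,0.8596,0.8217,1.1028,2.4722,0.5533,-0.1146,-0.9283,0.6538,1.1048,0.8814,-0.3205,-0.0665,1.3031,1.6772,1.1613,-0.0621,0.7702,0.839,0.995,0.907,435.7,26.5,431.3,0.0294,0.0594,0.5814,-0.729,22.0,24.0,22.0,21.0,AD,14.2,24.2,18,0.0,8.7
SYN00001,0.5944,0.1158,1.1133,0.4869,-0.1236,-0.2811,-0.8212,0.1911,-0.3503,-0.9664,-0.2348,0.4121,-0.1614,0.237,-0.056,-2.3648,-1.0273,-1.1316,-0.4561,-0.746,0.9758,-0.8639,0.9673,-1.5994,-0.6837,-0.1861,0.3336,0.5089,-0.0566,914.9,35.0,75.0,1.0692,-0.3268,0.0544,-0.4894,22.0,21.0,21.0,18.0,AD,5.1,35.9,22,0.5,6.6
SYN00002,-1.8397,-2.0867,-1.2896,-1.0751,-1.4819,0.0191,-1.6286,-0.8572,-0.5326,0.1824,-0.3616,0.7293,1.4586,1.9596,1.3133,1.0148,1.416,-0.4598,0.7511,-0.1204,0.1017,-0.926,1.2724,0.452,-1.0863,0.1293,1.4029,0.9404,2.5064,866.2,37.7,499.1,0.2686,0.198,-0.0042,1.2244,29.0,26.0,25.0,24.0,MCI-C,25.8,19.6,18,2.0,1.3
SYN00003,0.153,-1.7644,-1.527,-0.8434,-1.1801,-0.0959,-2.5067,-0.9108,0.7642,0.0326,2.1304,0.1237,-0.3557,-1.7637,0.0363,-0.7662,-0.958,-0.7796,0.3662,0.7444,-0.2431,-0.7092,-0.9278,-1.5655,-1.0649,0.1317,1.8174,-0.4541,0.8557,1317.2,39.9,251.3,-0.2804,-1.0927,-0.8249,0.6962,29.0,27.0,25.0,25.0,MCI-C,8.9,27.1,22,0.0,8.5
SYN00004,0.0517,0.702,1.2029,1.0684,1.022,1.2959,1.2603,0.0199,-1.4503,-2.3296,-0.565,-0.0935,0.0355,-0.8992,-0.4006,-1.2947,-0.1783,-0.44,0.2924,-1.0159,0.1908,0.2244,0.0181,-0.0815,-0.5666,-0.7378,-1.0985,0.0423,-0.3087,1029.2,59.8,1500.0,1.5487,2.1869,0.3379,-1.1806,30.0,29.0,30.0,29.0,MCI-NC,11.7,9.9,20,0.5,9.4
SYN00005,2.6381,2.009,1.6861,0.1659,1.4682,1.2098,0.4408,-0.1504,-2.436,-1.6202,2.4957,1.6767,1.0988,-0.1187,-0.1151,1.9564,1.345,1.2887,-0.2573,1.3289,1.2806,-0.4478,0.5977,0.949,0.537,0.1218,0.5229,0.6709,1.0045,914.1,50.7,543.1,1.9711,-0.5997,0.1435,1.1351,30.0,30.0,30.0,30.0,MCI-NC,27.0,20.4,23,2.0,9.0
SYN00006,-0.8576,0.0702,0.3302,-0.812,-0.0489,-0.0732,-0.397,-0.2699,-1.148,-2.1698,1.5528,-2.2098,0.1551,0.2447,0.6405,0.2259,-0.7673,0.7387,2.2248,-1.1531,1.2004,-0.2163,0.5182,-0.5753,-0.2095,1.0313,0.6742,1.9083,1.4392,896.9,43.0,152.4,0.01,-0.5423,-0.5648,0.0967,30.0,28.0,30.0,28.0,MCI-NC,17.7,18.3,29,2.0,5.7
SYN00007,0.0414,0.1253,0.0082,-0.5062,-1.3314,-0.5301,-0.5946,-0.2673,1.2087,-1.2799,0.6042,1.3118,0.6357,0.7049,0.0599,0.5079,0.0341,1.2074,-0.2911,0.6999,0.2333,0.9536,1.1129,1.7441,0.5969,-1.4566,0.0458,-0.6064,-0.0644,647.5,59.5,519.6,1.4597,0.6848,0.7475,-0.6795,27.0,28.0,24.0,25.0,,26.2,12.8,13,0.0,1.5
SYN00008,0.3031,-0.2793,-0.0821,0.7669,2.31,2.1804,-0.5585,0.5301,1.4518,2.7154,-0.0724,-1.1874,-1.89,-2.4096,-1.2382,-2.1392,-1.5175,-0.9331,0.0878,-1.0189,-3.0978,-1.3453,-1.0287,-1.0065,-0.2359,-3.4411,-1.9663,-0.7051,-2.5276,411.8,24.7,508.7,-0.8491,0.2835,0.1134,0.8787,24.0,23.0,25.0,27.0,MCI-NC,21.0,34.1,21,0.0,1.9
SYN00009,1.0397,-0.3564,0.248,-1.6859,-0.0367,0.1475,0.9438,0.1335,-1.1119,0.9778,1.3763,0.6516,1.7455,0.2458,0.9065,0.1994,0.0918,-0.6963,0.644,0.6921,0.4678,2.8205,1.5741,-0.0508,1.4069,0.7232,0.8022,0.751,1.5803,592.4,22.2,360.6,-0.426,0.7365,-0.5052,-0.6906,27.0,28.0,30.0,29.0,CN,23.5,20.1,18,1.0,9.3
SYN00010,1.8303,-1.3842,0.502,-1.8898,0.5315,-0.2347,-1.8324,0.1612,1.0744,0.4238,-0.618,1.4392,-0.2986,-0.5373,2.0073,0.2733,1.8109,0.3047,1.2548,0.2184,-0.2395,-0.2625,0.1988,-0.7683,0.8628,1.1618,0.5367,-0.4536,0.6321,1092.0,42.6,286.4,0.022,0.8451,-0.4732,1.6695,30.0,30.0,NA,28.0,CN,7.3,39.3,17,0.0,5.5
SYN00011,2.3031,0.4018,0.8625,-0.7784,0.7227,1.3688,0.6769,0.8539,0.9588,2.2605,-0.0078,1.9165,-0.2909,-0.2388,-1.2471,-0.5796,2.3375,1.5617,0.7515,-0.4066,-1.9926,0.5195,2.4484,0.8926,0.4224,1.2275,-0.4913,0.1218,0.9201,600.6,17.0,275.3,-0.7785,0.7021,-1.8913,-0.2469,30.0,30.0,30.0,30.0,CN,18.5,26.9,14,0.5,1.8
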