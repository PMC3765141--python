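row,row_kind,low_ha,medium_ha,high_ha,very_high_ha,low_pct,medium_pct,high_pct,very_high_pct
1.1.1,indicator,10264750,171285,0,2542545,79,1,0,20
1.1.2,indicator,8002697,0,4975900,0,62,0,38,0
1.1.3,indicator,6180760,1531902,4093223,1411301,47,12,31,11
1.2.1,indicator,4888399,7866970,307058,156690,37,60,2,1
1.2.2,indicator,8820942,3181400,814944,401832,67,24,6,3
1.2.4,indicator,8411319,0,2738594,2061619,64,0,21,16
3.1.1,indicator,7369502,10780,594496,5244338,56,0,4,40
rim,combined,2615081,0,1256493,9107006,20,0,10,70
rim_inactive_concessions,zone,916000,0,523886,2054963,7,0,4,16
rim_other_use_outside_concessions,zone,521802,0,180936,1068394,4,0,1,8
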