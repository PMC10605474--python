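patient_id,sb_allele1,sb_allele2,sb_homozygous,ogm_mean1,ogm_sd1,ogm_mean2,ogm_sd2,ogm_homozygous
Pt1,765,1242,0,677,41,955,45,0
Pt2,598,1035,0,622,34,841,36,0
Pt3,989,,1,894,29,,,1
Pt4,1127,1593,0,866,48,1182,70,0
Pt5,1447,1838,0,1017,57,1180,40,0
Pt6,917,,1,664,24,730,22,0
Pt7,1400,,1,1223,36,,,1
Pt8,991,,1,829,53,,,1
Pt9,1185,,1,880,46,943,29,0
Pt10,1256,4746,0,1055,79,3226,163,0
Pt11,249,810,0,333,20,831,35,0
Pt12,724,,1,792,63,,,1
Pt13,294,,1,406,32,,,1
Pt14,640,794,0,652,40,759,24,0
Pt15,605,714,0,640,51,,,1
Pt16,794,2386,0,745,51,1646,97,0
Pt17,810,,1,582,35,654,24,0
Control1,,,0,-4,26,450,22,0
Control2,,,0,-6,30,,,1
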