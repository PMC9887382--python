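cohort,variable,level,count,percent
overall,sex,female,1350,61.5
overall,sex,male,846,38.5
overall,age_band,<65,133,6.1
overall,age_band,65-69,154,7.0
overall,age_band,70-74,312,14.2
overall,age_band,75-79,407,18.5
overall,age_band,80-84,515,23.5
overall,age_band,85+,675,30.7
overall,ethnicity,white,1104,50.3
overall,ethnicity,not_white,959,43.7
overall,ethnicity,not_reported,133,6.1
overall,smoker,yes,149,6.8
overall,smoker,no_or_unknown,2047,93.2
overall,va_ge70,yes,563,25.6
overall,va_ge70,no,1633,74.4
overall,va_le20,yes,55,2.5
overall,va_le20,no,2141,97.5
overall,va_lt25,yes,139,6.3
overall,va_lt25,no,2057,93.7
MEH,sex,female,1167,60.5
MEH,sex,male,762,39.5
MEH,age_band,<65,125,6.5
MEH,age_band,65-69,139,7.2
MEH,age_band,70-74,271,14.0
MEH,age_band,75-79,369,19.1
MEH,age_band,80-84,447,23.2
MEH,age_band,85+,578,30.0
MEH,ethnicity,white,905,46.9
MEH,ethnicity,not_white,945,49.0
MEH,ethnicity,not_reported,79,4.1
MEH,smoker,yes,140,7.3
MEH,smoker,no_or_unknown,1789,92.7
MEH,va_ge70,yes,503,26.1
MEH,va_ge70,no,1426,73.9
MEH,va_le20,yes,40,2.1
MEH,va_le20,no,1889,97.9
MEH,va_lt25,yes,112,5.8
MEH,va_lt25,no,1817,94.2
UHB,sex,female,183,68.5
UHB,sex,male,84,31.5
UHB,age_band,<65,8,3.0
UHB,age_band,65-69,15,5.6
UHB,age_band,70-74,41,15.4
UHB,age_band,75-79,38,14.2
UHB,age_band,80-84,68,25.5
UHB,age_band,85+,97,36.3
UHB,ethnicity,white,199,74.5
UHB,ethnicity,not_white,14,5.2
UHB,ethnicity,not_reported,54,20.2
UHB,smoker,yes,9,3.4
UHB,smoker,no_or_unknown,258,96.6
UHB,va_ge70,yes,60,22.5
UHB,va_ge70,no,207,77.5
UHB,va_le20,yes,15,5.6
UHB,va_le20,no,252,94.4
UHB,va_lt25,yes,27,10.1
UHB,va_lt25,no,240,89.9
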