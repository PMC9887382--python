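cohort,variable,level,count,percent
marina_sham,sex,female,159,66.8
marina_sham,sex,male,79,33.2
marina_sham,age_band,<65,11,4.6
marina_sham,age_band,65-69,17,7.1
marina_sham,age_band,70-74,50,21.0
marina_sham,age_band,75-79,68,28.6
marina_sham,age_band,80-84,64,26.9
marina_sham,age_band,85+,26,10.9
marina_sham,ethnicity,white,231,97.1
marina_sham,ethnicity,not_white,7,2.9
marina_sham,smoker,yes,130,54.6
marina_sham,smoker,no_or_unknown,108,45.4
marina_sham,va_ge70,yes,22,9.2
marina_sham,va_ge70,no,216,90.8
marina_sham,va_le20,yes,4,1.7
marina_sham,va_le20,no,234,98.3
marina_sham,va_lt25,yes,9,3.8
marina_sham,va_lt25,no,229,96.2
meh_matched,sex,female,128,59.5
meh_matched,sex,male,87,40.5
meh_matched,age_band,<65,9,4.2
meh_matched,age_band,65-69,19,8.8
meh_matched,age_band,70-74,37,17.2
meh_matched,age_band,75-79,58,27.0
meh_matched,age_band,80-84,60,27.9
meh_matched,age_band,85+,32,14.9
meh_matched,ethnicity,white,97,45.1
meh_matched,ethnicity,not_white,118,54.9
meh_matched,smoker,yes,110,51.2
meh_matched,smoker,no_or_unknown,105,48.8
meh_matched,va_ge70,yes,16,7.4
meh_matched,va_ge70,no,199,92.6
meh_matched,va_le20,yes,3,1.4
meh_matched,va_le20,no,212,98.6
meh_matched,va_lt25,yes,12,5.6
meh_matched,va_lt25,no,203,94.4
meh_unmatched,sex,female,73,66.4
meh_unmatched,sex,male,37,33.6
meh_unmatched,age_band,<65,6,5.5
meh_unmatched,age_band,65-69,4,3.6
meh_unmatched,age_band,70-74,14,12.7
meh_unmatched,age_band,75-79,13,11.8
meh_unmatched,age_band,80-84,20,18.2
meh_unmatched,age_band,85+,53,48.2
meh_unmatched,ethnicity,white,55,50.0
meh_unmatched,ethnicity,not_white,55,50.0
meh_unmatched,smoker,yes,55,50.0
meh_unmatched,smoker,no_or_unknown,55,50.0
meh_unmatched,va_ge70,yes,61,55.5
meh_unmatched,va_ge70,no,49,44.5
meh_unmatched,va_le20,yes,3,2.7
meh_unmatched,va_le20,no,107,97.3
meh_unmatched,va_lt25,yes,7,6.4
meh_unmatched,va_lt25,no,103,93.6
uhb_matched,sex,female,32,72.7
uhb_matched,sex,male,12,27.3
uhb_matched,age_band,<65,2,4.5
uhb_matched,age_band,65-69,1,2.3
uhb_matched,age_band,70-74,4,9.1
uhb_matched,age_band,75-79,4,9.1
uhb_matched,age_band,80-84,19,43.2
uhb_matched,age_band,85+,14,31.8
uhb_matched,ethnicity,white,39,88.6
uhb_matched,ethnicity,not_white,5,11.4
uhb_matched,smoker,yes,33,75.0
uhb_matched,smoker,no_or_unknown,11,25.0
uhb_matched,va_ge70,yes,8,18.2
uhb_matched,va_ge70,no,36,81.8
uhb_matched,va_le20,yes,1,2.3
uhb_matched,va_le20,no,43,97.7
uhb_matched,va_lt25,yes,1,2.3
uhb_matched,va_lt25,no,43,97.7
uhb_unmatched,sex,female,7,100.0
uhb_unmatched,sex,male,0,0.0
uhb_unmatched,age_band,<65,0,0.0
uhb_unmatched,age_band,65-69,0,0.0
uhb_unmatched,age_band,70-74,0,0.0
uhb_unmatched,age_band,75-79,0,0.0
uhb_unmatched,age_band,80-84,0,0.0
uhb_unmatched,age_band,85+,7,100.0
uhb_unmatched,ethnicity,white,6,85.7
uhb_unmatched,ethnicity,not_white,1,14.3
uhb_unmatched,smoker,yes,3,42.9
uhb_unmatched,smoker,no_or_unknown,4,57.1
uhb_unmatched,va_ge70,yes,1,14.3
uhb_unmatched,va_ge70,no,6,85.7
uhb_unmatched,va_le20,yes,1,14.3
uhb_unmatched,va_le20,no,6,85.7
uhb_unmatched,va_lt25,yes,1,14.3
uhb_unmatched,va_lt25,no,6,85.7
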