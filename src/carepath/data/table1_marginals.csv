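table,row_label,variable,level,overall_n,overall_pct,healthy_n,healthy_pct,sick_n,sick_pct,note
T1,Mother's age <20,mother_age,<20,2629,15.2,1281,15.1,1348,15.4,
T1,Mother's age 20-34,mother_age,20-34,13263,76.9,6524,76.9,6739,76.9,
T1,Mother's age 35-49,mother_age,35-49,1359,7.9,681,8.0,678,7.7,
T1,No education,education,no_education,1267,7.3,696,8.2,571,6.5,
T1,Primary incomplete,education,primary_incomplete,2164,12.5,1074,12.7,1090,12.4,
T1,Primary complete,education,primary_complete,2643,15.3,1364,16.1,1279,14.6,
T1,Secondary incomplete,education,secondary_incomplete,7507,43.5,3567,42.0,3940,45.0,
T1,Secondary complete or higher,education,secondary_complete_or_higher,3670,21.3,1785,21.0,1885,21.5,
T1,Wealth Lowest,wealth,lowest,3319,19.2,1638,19.3,1681,19.2,
T1,Wealth Second,wealth,second,3353,19.4,1666,19.6,1687,19.2,
T1,Wealth Middle,wealth,middle,3473,20.1,1691,19.9,1782,20.3,
T1,Wealth Fourth,wealth,fourth,3519,20.4,1696,20.0,1823,20.8,
T1,Wealth Highest,wealth,highest,3587,20.8,1795,21.2,1792,20.4,
T1,Living children 1,living_children,1,5992,34.7,2860,33.7,3132,35.7,
T1,Living children 2-3,living_children,2-3,9302,53.9,4615,54.4,4687,53.5,
T1,Living children 4+,living_children,4+,1957,11.3,1011,11.9,946,10.8,
T1,History of child mortality No,child_death_history,no,15524,90.0,7644,90.1,7880,89.9,
T1,History of child mortality Yes,child_death_history,yes,1727,10.0,842,9.9,885,10.1,
T1,Sex of child Female,newborn_sex,female,8882,51.5,4603,54.2,4279,48.8,
T1,Sex of child Male,newborn_sex,male,8369,48.5,3883,45.8,4486,51.2,
T1,CHW's home visit during ANC No,chw_visit,no,14193,82.3,7163,84.4,7030,80.2,
T1,CHW's home visit during ANC Yes,chw_visit,yes,3058,17.7,1323,15.6,1735,19.8,
T1,Distance <=5 km,facility_distance,under_5km,8146,47.2,3980,46.9,4166,47.5,
T1,Distance 5+ km,facility_distance,5km_plus,9105,52.8,4506,53.1,4599,52.5,
T1,Danger sign counseling during PNC period No,ds_counseling,no,13011,75.4,6574,77.5,6437,73.4,
T1,Danger sign counseling during PNC period Yes,ds_counseling,yes,4240,24.6,1912,22.5,2328,26.6,
T1,4+ANC from qualified providers No,anc4,no,12540,72.7,6360,74.9,6180,70.5,
T1,4+ANC from qualified providers Yes,anc4,yes,4711,27.3,2126,25.1,2585,29.5,
T1,Facility delivery No,facility_delivery,no,8254,47.8,4147,48.9,4107,46.9,
T1,Facility delivery Yes,facility_delivery,yes,8997,52.2,4339,51.1,4658,53.1,
T1,PNC from qualified providers No,pnc,no,9765,56.6,4877,57.5,4888,55.8,
T1,PNC from qualified providers Yes,pnc,yes,7486,43.4,3609,42.5,3877,44.2,
T1,Care-seeking for recent maternal complication No,maternal_careseeking,no,14188,35.0,7399,36.8,6789,34.0,printed row is internally inconsistent: counts include women without a complication while percentages refer to the N=4713 complication subset
T1,Care-seeking for recent maternal complication Yes,maternal_careseeking,yes,3063,65.0,1087,63.2,1976,66.0,printed row is internally inconsistent: counts include women without a complication while percentages refer to the N=4713 complication subset
T1,Knowledge 0,knowledge,0,589,3.4,301,3.5,288,3.3,
T1,Knowledge 1-4,knowledge,1-4,13618,78.9,6919,81.5,6699,76.4,
T1,Knowledge 5+,knowledge,5+,3044,17.6,1266,14.9,1778,20.3,
T1,Care-seeking for neonatal danger sign No,neonatal_careseeking_any,no,,,,,457,5.2,asked only for sick neonates
T1,Care-seeking for neonatal danger sign Yes,neonatal_careseeking_any,yes,,,,,8308,94.8,asked only for sick neonates
T1,No care-seeking,neonatal_careseeking_provider,none,,,,,457,5.2,asked only for sick neonates
T1,Care-seeking from unqualified providers,neonatal_careseeking_provider,unqualified,,,,,5110,58.3,asked only for sick neonates
T1,Care-seeking from qualified providers,neonatal_careseeking_provider,qualified,,,,,3198,36.5,asked only for sick neonates
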