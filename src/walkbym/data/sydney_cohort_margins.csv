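variable,stratum,N,n_overweight,n_obese,pct_overweight,pct_obese
cohort,all,92157,35934,18876,49.0,33.6
walkability,low,25454,10150,6251,52.9,40.8
walkability,low-medium,31404,12380,6655,50.0,35.0
walkability,medium-high,19449,7543,3454,47.2,29.0
walkability,high,15850,5861,2516,44.0,25.2
disadvantage,Q1-most,17425,6697,4559,52.1,42.5
disadvantage,Q2,19517,7579,4847,51.7,40.6
disadvantage,Q3-middling,14984,5877,3082,49.4,33.8
disadvantage,Q4,19982,7938,3392,47.8,28.2
disadvantage,Q5-least,20249,7843,2996,45.5,24.1
sex,male,44690,20802,8912,58.1,37.3
sex,female,47467,15132,9964,40.3,30.8
age_group,45-49,13550,4871,2761,45.1,31.8
age_group,50-54,16723,6188,3665,47.4,34.8
age_group,55-59,16717,6568,3885,51.2,38.3
age_group,60-64,13742,5696,3136,53.7,39.0
age_group,65-69,10188,4297,2227,54.0,37.8
age_group,70-74,6910,2969,1341,53.3,34.0
age_group,75-79,4999,2047,820,49.0,27.8
age_group,80-84,6614,2513,801,43.2,19.5
age_group,85+,2714,785,240,31.7,12.4
language,english,78028,30768,16330,49.9,34.6
language,other,14129,5166,2546,44.6,28.4
education,less_than_secondary,7434,2704,2086,50.6,44.1
education,secondary,26741,10171,6052,49.2,36.5
education,trade_certificate,28932,11814,6143,51.8,35.9
education,university,29050,11245,4595,46.0,25.8
relationship,partner,68759,27826,13863,50.7,33.9
relationship,no_partner,23398,8108,5013,44.1,32.8
employment,full_time,32716,13622,7246,53.5,37.9
employment,part_time,13177,4418,2408,41.0,27.5
employment,other_work,1358,426,281,39.6,30.2
employment,not_working,44906,17468,8941,48.6,32.6
insurance,private_extras,54218,21751,10830,50.1,33.4
insurance,private_no_extras,12961,5058,2255,47.2,28.5
insurance,health_care_card,11993,4351,2881,47.8,37.7
insurance,none,12985,4774,2910,47.4,35.4
smoking,never,54117,20518,10072,46.6,30.0
smoking,past,31639,13145,7397,54.2,40.0
smoking,current,6401,2271,1407,45.5,34.1
distress,low,70218,27960,13318,49.1,31.5
distress,moderate,14573,5433,3475,49.0,38.0
distress,high,5152,1828,1375,48.4,41.4
distress,very_high,2214,713,708,47.3,47.2
diagnosed_conditions,0,31297,11955,4218,44.1,21.8
diagnosed_conditions,1,36917,14726,7560,50.2,34.1
diagnosed_conditions,2,18186,7145,5040,54.4,45.6
diagnosed_conditions,3+,5757,2108,2058,57.0,56.4
treated_conditions,0,41580,15904,6590,45.5,25.7
treated_conditions,1,30121,12141,6448,51.3,35.9
treated_conditions,2,14524,5721,3835,53.5,43.6
treated_conditions,3+,5932,2168,2003,55.2,53.2
functional_limitation,none,32392,12656,3908,44.4,19.8
functional_limitation,minor,25125,10628,4838,52.4,33.4
functional_limitation,moderate,20316,7801,5555,52.8,44.4
functional_limitation,severe,14324,4849,4575,49.7,48.3
total_physical_activity,0min,5478,1868,1807,50.9,50.1
total_physical_activity,1-149min,15365,5895,4053,52.1,42.8
total_physical_activity,150-299min,15833,6241,3468,50.5,36.2
total_physical_activity,300min+,55481,21930,9548,47.7,28.5
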