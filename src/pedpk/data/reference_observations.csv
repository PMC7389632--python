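label,metric,value,weight,route,dose_mg,n_doses,tau_h,fed,window_h,day
iv_auc72_2.97,auc_last,682,1.0,iv_bolus,2.97,1,24,0,72,
iv_auc72_5.53,auc_last,1026,0.0,iv_bolus,5.53,1,24,0,72,
iv_auc72_11.20,auc_last,1884,0.0,iv_bolus,11.20,1,24,0,72,
vss_iv,vss,0.89,1.0,iv_bolus,2.97,1,24,0,,
oral_fast_cmax,cmax,86,1.0,oral,20,1,24,0,,
oral_fast_tmax,tmax,6.2,0.5,oral,20,1,24,0,,
oral_fast_auc120,auc_last,1231,1.0,oral,20,1,24,0,120,
oral_fast_cmax_beermann,cmax,79.8,0.0,oral,20,1,24,0,,
oral_fast_tmax_beermann,tmax,6.5,0.0,oral,20,1,24,0,,
oral_fast_auc72_beermann,auc_last,992.8,0.0,oral,20,1,24,0,72,
oral_fed_cmax,cmax,69,1.0,oral,20,1,24,1,,
oral_fed_tmax,tmax,6.8,0.5,oral,20,1,24,1,,
oral_fed_auc120,auc_last,1029,0.0,oral,20,1,24,1,120,
cmin_day1,cmin_day,8.40,1.0,oral,20,10,24,0,,1
cmin_day2,cmin_day,11.45,0.0,oral,20,10,24,0,,2
cmin_day3,cmin_day,12.20,0.0,oral,20,10,24,0,,3
cmin_day4,cmin_day,12.40,0.0,oral,20,10,24,0,,4
cmin_day5,cmin_day,12.48,0.0,oral,20,10,24,0,,5
cmin_day6,cmin_day,12.53,0.0,oral,20,10,24,0,,6
cmin_day7,cmin_day,12.57,0.0,oral,20,10,24,0,,7
cmin_day8,cmin_day,12.60,0.0,oral,20,10,24,0,,8
cmin_day9,cmin_day,12.63,0.0,oral,20,10,24,0,,9
cmin_day10,cmin_day,12.79,1.0,oral,20,10,24,0,,10
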