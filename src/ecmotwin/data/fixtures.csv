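row_id,kind,arterial_fr,drainage_fr,svr,pvr,hr,mode,omega_rpm,q_set,observed_field,value,sigma_scale,ref_row,location
b_co_2500,value,15,21,2500,100,80,baseline,0,0,co,2.0,1.0,,"Methods: baseline SVR 2500 -> CO 2 L/min"
b_map_2500,value,15,21,2500,100,80,baseline,0,0,map,67.0,1.0,,"Methods: baseline SVR 2500 -> MAP 67 mmHg"
b_co_1600,value,15,21,1600,100,80,baseline,0,0,co,2.6,1.0,,"Methods: SVR 1600 -> 2.6 L/min CO"
b_map_1600,value,15,21,1600,100,80,baseline,0,0,map,56.6,1.0,,"Methods: SVR 1600 -> 56.6 mmHg MAP"
b_co_1000,value,15,21,1000,100,80,baseline,0,0,co,3.2,1.0,,"Methods: SVR 1000 -> 3.2 L/min CO"
b_map_1000,value,15,21,1000,100,80,baseline,0,0,map,47.2,1.0,,"Methods: SVR 1000 -> 47.2 mmHg MAP"
f_inlet_15_1600,value,15,21,1600,100,80,flow,0,3.0,inlet_pressure,253.3,1.0,,"Results: 15 Fr supplied 3 L/min at 253.3 mmHg inlet"
f_inlet_15_2500,value,15,21,2500,100,80,flow,0,3.0,inlet_pressure,293.9,1.0,,"Results: 15 Fr at 3 L/min, high SVR -> 293.9 mmHg"
f_inlet_15_1000,value,15,21,1000,100,80,flow,0,3.0,inlet_pressure,241.7,1.0,,"Results: 15 Fr at 3 L/min, low SVR -> 241.7 mmHg"
f_sat_13,gt,13,21,1600,100,80,flow,0,3.0,inlet_pressure,357.0,1.0,,"Results: 13 Fr reached 3 L/min only beyond the 357 mmHg transducer limit"
f_sub300_17,lt,17,21,1600,100,80,flow,0,4.0,inlet_pressure,300.0,1.0,,"Results: 17-21 Fr achieved 4 L/min below 300 mmHg"
f_sub300_19,lt,19,21,1600,100,80,flow,0,4.0,inlet_pressure,300.0,1.0,,"Results: 17-21 Fr achieved 4 L/min below 300 mmHg"
f_sub300_21,lt,21,21,1600,100,80,flow,0,4.0,inlet_pressure,300.0,1.0,,"Results: 17-21 Fr achieved 4 L/min below 300 mmHg"
f_map_q4,value,15,21,1600,100,80,flow,0,4.0,map,90.8,1.0,,"Discussion: 4 L/min ECMO flow with MAP 90.8 mmHg (15 Fr)"
f_total_q4,value,15,21,1600,100,80,flow,0,4.0,total_flow,4.4,1.0,,"Discussion: ... and total flow of 4.4 L/min (15 Fr)"
s_map_3830,value,15,21,1600,100,80,speed,3830,0,map,81.1,1.0,,"Results: MAP of 81.1 mmHg at a pump speed of 3830 rpm"
s_map_2970,value,15,21,1600,100,80,speed,2970,0,map,73.8,1.0,,"Results: 73.8 mmHg at 2970 rpm"
s_max_15_1600,value,15,21,1600,100,80,speed,4500,0,q_ecmo,3.8,1.0,,"Results: maximum circuit flow 3.8 L/min at 4500 rpm (15 Fr)"
s_max_15_2500,value,15,21,2500,100,80,speed,4500,0,q_ecmo,3.6,1.0,,"Results: max ECMO flow 3.6 L/min at high SVR (15 Fr)"
s_max_15_1000,value,15,21,1000,100,80,speed,4500,0,q_ecmo,3.9,1.0,,"Results: max ECMO flow rose to 3.9 L/min at low SVR (15 Fr)"
s_q3_17_3310,value,17,21,1600,100,80,speed,3310,0,q_ecmo,3.0,1.0,,"Discussion: 3310 rpm generated 3 L/min with 17 Fr arterial / 21 Fr drainage"
s_max_21_1600,value,21,21,1600,100,80,speed,4500,0,q_ecmo,5.0,2.0,,"Results: 21 Fr arterial enabled maximum flow rates up to 5 L/min"
d_qmax_15,diff,15,25,1600,100,80,speed,4500,0,q_ecmo,0.2,1.0,s_max_15_1600,"Results: max flow increased by only 0.2 L/min (21->25 Fr drainage, 15 Fr arterial)"
d_qmax_21,diff,21,25,1600,100,80,speed,4500,0,q_ecmo,0.8,1.0,s_max_21_1600,"Results: max flow increased by 0.8 L/min (21->25 Fr drainage, 21 Fr arterial)"
d_total_15,diff,15,25,1600,100,80,speed,4500,0,total_flow,0.1,1.0,s_max_15_1600,"Results: 0.1 L/min total-flow difference between 21 and 25 Fr drainage (15 Fr arterial)"
d_map_15,diff,15,25,1600,100,80,speed,4500,0,map,0.9,1.0,s_max_15_1600,"Results: 0.9 mmHg MAP difference between 21 and 25 Fr drainage (15 Fr arterial)"
d_total_21,diff,21,25,1600,100,80,speed,4500,0,total_flow,1.1,1.0,s_max_21_1600,"Results: 1.1 L/min total-flow difference (21 Fr arterial, max speed)"
d_map_21,diff,21,25,1600,100,80,speed,4500,0,map,21.3,1.0,s_max_21_1600,"Results: 21.3 mmHg MAP difference (21 Fr arterial, max speed)"
r_collapse_21_21,lt,21,21,2500,100,80,speed,4500,0,rap,0.0,1.0,,"Discussion: 21 Fr arterial at max speed, high SVR -> RAP <= 0 (collapse surrogate)"
r_collapse_21_23,lt,21,23,2500,100,80,speed,4500,0,rap,0.0,1.0,,"Discussion: collapse surrogate with all drainage sizes (23 Fr)"
r_collapse_21_25,lt,21,25,2500,100,80,speed,4500,0,rap,0.0,1.0,,"Discussion: collapse surrogate with all drainage sizes (25 Fr)"
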