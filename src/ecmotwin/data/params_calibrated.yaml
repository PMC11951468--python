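emax_lv: 0.5181632988407349
emin_lv: 0.07202029017471348
v_total: 688.6914069186287
r_valve: 0.21597438282325823
l_art: 0.10016025588729759
k2_art_ref: 17.536431438053686
l_drain: 0.3000014194476804
k2_drain_ref: 6.796533199756997
drain_exp: 5.999970889672008
k1_ox: 1.007250229632604
a2: 34.72231645690597
a1: -10.396567658577117
a0: -0.136982190366254
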