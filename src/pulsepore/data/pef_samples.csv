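sample_id,pulse_width_ns,field_strength_kv_cm,yp_rate,pi_rate,fusion_rate,role
W_200ns_E_2.0_,200,2.0,78,8,1.10,train
W_200ns_E_2.4_,200,2.4,83,12,2.50,train
W_1000ns_E_0.0_,1000,0.0,14,10,0.25,train
W_1000ns_E_2.4_,1000,2.4,85,46,3.50,train
W_10us_E_0.0_,10000,0.0,12,10,0.36,train
W_10us_E_2.0_,10000,2.0,81,53,4.20,train
W_40us_E_0.0_,40000,0.0,10,8,0.31,train
W_40us_E_2.4_,40000,2.4,90,82,20.6,train
W_200ns_E_0.0_,200,0.0,13,10,0.28,test
W_1000ns_E_2.0_,1000,2.0,82,38,1.60,test
W_10us_E_2.4_,10000,2.4,86,62,8.30,test
W_40us_E_2.0_,40000,2.0,87,76,13.3,test
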