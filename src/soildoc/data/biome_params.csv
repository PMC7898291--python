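biome,kp_day,kdoc_labile_day,kdoc_recalcitrant_day,cue,q10,t_ref_k,dpm_fraction,sorb_a0,sorb_a1,sorb_a2,d_coeff_m2_s,clay,silt,ph,zstar_m,s_wilt,s_opt,kp_lo,kp_hi,kdoc_lo,kdoc_hi,kp_optimized,kdoc_optimized
boreal,1.0,600,600,0.5,2.0,298.15,0.25,0.0,-0.1,1.5,1.06e-9,0.12,0.40,4.8,0.25,0.15,0.70,1.0,2.0,820,4545,1.24,3284
temperate,1.0,600,600,0.5,2.0,298.15,0.25,0.0,-0.1,1.5,1.06e-9,0.20,0.35,5.5,0.35,0.15,0.70,1.0,2.0,602,2127,1.0,611
tropical,1.0,600,600,0.5,2.0,298.15,0.25,0.0,-0.1,1.5,1.06e-9,0.30,0.30,4.5,0.45,0.15,0.70,1.0,2.0,609,819,1.9,636
grass,1.0,600,600,0.5,2.0,298.15,0.25,0.0,-0.1,1.5,1.06e-9,0.22,0.38,6.2,0.30,0.15,0.70,1.0,2.0,500,1000,1.2,601
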