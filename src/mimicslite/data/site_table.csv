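site_id,litterfall,soil_t_mean,soil_t_sd,moisture_mean,moisture_sd,mult_max,mult_min,clay_pct,lignin_n_1,lignin_n_2,lignin_n_3,role
TREE,519,6.8,10.8,0.44,0.27,1.10,0.90,5,12,30,32,calibration
BART,613,8.5,9.3,0.55,0.29,1.07,0.93,12,15,34,40,calibration
HARV,637,8.9,9.1,0.66,0.25,1.06,0.94,16,27,33,65,calibration
GRSM,853,14.7,6.5,0.80,0.06,1.06,0.94,16,21,25,43,calibration
SERC,744,14.8,8.0,0.62,0.09,1.03,0.97,12,15,20,33,calibration
TALL,608,18.1,6.3,0.66,0.11,1.08,0.92,3,25,37,112,calibration
LENO,841,19.1,6.1,0.71,0.12,1.03,0.97,21,32,35,54,calibration
UNDE,591,6.1,10.3,0.47,0.32,1.07,0.93,6,13,31,34,validation
MLBS,639,9.5,7.5,0.70,0.19,1.03,0.97,11,6,26,37,validation
SCBI,640,13.0,8.1,0.61,0.11,1.06,0.94,32,13,17,34,validation
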