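phase,diet,initial_bw_g,initial_bw_se,final_bw_g,final_bw_se,feed_intake_g_d,feed_intake_se,n_intake_mg_d,n_intake_se,n_excretion_mg_d,n_excretion_se,n_retention_mg_d,n_retention_se,creatinine_mg_d,creatinine_se
week6_7,low_nitrogen,519.509,18.419,523.273,17.022,40.627,2.2,520.136,26.545,359.478,4.986,160.658,8.717,1.535,0.061
week6_7,nitrogen_free,487.82,8.759,421.379,6.387,20.961,0.893,18.781,0.799,217.567,8.486,,,,
week11_12,low_nitrogen,867.936,6.983,885.757,12.839,240.315,5.779,724.789,17.431,346.966,14.3,377.823,18.502,2.124,0.05
week11_12,nitrogen_free,873.221,8.283,840.339,5.563,161.983,12.156,36.284,2.722,239.645,19.991,,,,
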