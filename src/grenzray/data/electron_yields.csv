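energy_ev,source,let_kev_um,bd_pct,ssb_pct,ssbp_pct,twossb_pct,dsb_pct,dsbp_pct,dsbpp_pct,total_ssb,total_dsb
100,mcds,21.47,44.1,32.9,8.3,3.77,4.72,3.19,3.02,102.4 ± 0.1,24.9 ± 0.1
100,track_structure,21.47,73.9,22.4,1.9,0.09,1.39,0.27,0.02,162.5,9.8
300,mcds,16.95,55.2,33.0,4.9,1.52,3.33,1.42,0.65,139.5 ± 0.1,19.1 ± 0.1
300,track_structure,16.95,66.4,26.6,3.3,0.43,2.38,0.85,0.09,162.5,15.0
500,mcds,14.12,59.5,32.1,3.6,0.92,2.67,0.88,0.29,154.2 ± 0.1,16.1 ± 0.1
500,track_structure,14.12,68.7,24.4,2.8,0.47,1.86,0.79,0.07,162.5,13.0
1000,mcds,10.28,63.5,30.9,2.5,0.50,2.00,0.48,0.11,168.6 ± 0.1,12.9 ± 0.1
1000,track_structure,10.28,68.9,25.2,2.8,0.50,1.81,0.71,0.08,156.0,13.0
1500,mcds,8.25,65.1,30.3,2.1,0.37,1.74,0.36,0.07,174.3 ± 0.1,11.5 ± 0.1
1500,track_structure,8.25,70.5,24.3,2.4,0.40,1.69,0.63,0.07,156.0,11.7
4500,mcds,4.08,66.2,29.9,1.8,0.20,1.60,0.30,0.05,123.5,7.7
4500,track_structure,4.08,71.4,24.1,2.1,0.29,1.47,0.55,0.04,123.5,7.8
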