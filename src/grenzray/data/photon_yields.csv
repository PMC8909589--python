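quality,o2_percent,source,mean_energy_kv,bd_pct,ssb_pct,ssbp_pct,twossb_pct,dsb_pct,dsbp_pct,dsbpp_pct,total_ssb,total_dsb
15 kV,21,mcds,15,66.9,29.4,1.6,0.3,1.4,0.3,0.1,184.5 ± 0.1,8.9 ± 0.1
10 kV,21,mcds,10,66.0,29.7,1.9,0.4,1.6,0.3,0.1,182.7 ± 0.1,9.3 ± 0.1
10 kVp,21,mcds,5.7,64.4,30.3,2.3,0.5,1.8,0.5,0.2,179.1 ± 0.1,10.2 ± 0.1
4.55 kV,21,mcds,4.55,63.5,30.5,2.6,0.6,2.0,0.6,0.2,176.9 ± 0.1,10.8 ± 0.1
4.55 kV,21,track_structure,4.55,75.2,21.9,1.3,0.4,0.9,0.2,0.0,,
Co-60,21,mcds,1250,68.4,28.8,1.3,0.2,1.1,0.2,0.0,187.4 ± 0.1,8.1 ± 0.1
15 kV,2,mcds,15,67.6,29.1,1.5,0.2,1.3,0.2,0.1,171.1 ± 0.1,7.5 ± 0.1
10 kV,2,mcds,10,66.8,29.4,1.7,0.3,1.4,0.3,0.1,169.7 ± 0.1,7.9 ± 0.1
10 kVp,2,mcds,5.7,65.2,30.0,2.1,0.4,1.7,0.4,0.2,166.8 ± 0.1,8.7 ± 0.1
4.55 kV,2,mcds,4.55,64.4,30.3,2.3,0.5,1.8,0.5,0.2,165.0 ± 0.1,9.2 ± 0.1
Co-60,2,mcds,1250,69.0,28.5,1.2,0.2,1.0,0.1,0.0,173.5 ± 0.1,6.9 ± 0.1
15 kV,0.1,mcds,15,69.8,28.1,1.0,0.1,0.9,0.1,0.0,126.0 ± 0.1,3.8 ± 0.1
10 kV,0.1,mcds,10,69.1,28.3,1.2,0.2,1.0,0.2,0.0,125.4 ± 0.1,4.1 ± 0.1
10 kVp,0.1,mcds,5.7,67.8,28.8,1.5,0.3,1.2,0.3,0.1,124.3 ± 0.1,4.6 ± 0.1
4.55 kV,0.1,mcds,4.55,67.1,29.2,1.7,0.3,1.4,0.3,0.1,123.8 ± 0.1,4.9 ± 0.1
Co-60,0.1,mcds,1250,70.9,27.5,0.8,0.1,0.7,0.1,0.0,127.0 ± 0.1,3.5 ± 0.1
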