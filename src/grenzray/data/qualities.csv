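quality,mean_energy_kv,let_kev_um,measured_dsb,measured_rbe,dsb_yield,rbe
15 kV,15,2.7,,,8.9 ± 0.1,1.1 ± 0.0
10 kV,10,3.7,,,9.3 ± 0.1,1.2 ± 0.0
10 kVp,5.7,5.6,,,10.2 ± 0.1,1.3 ± 0.0
4.55 kV,4.55,6.6,10.4,1.4,10.8 ± 0.1,1.3 ± 0.0
Co-60,1250,0.24,7.6,1.0,8.1 ± 0.1,
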