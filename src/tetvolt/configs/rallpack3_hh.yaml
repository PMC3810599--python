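# Squid Hodgkin-Huxley cable (Rallpack 3 parameters, conventional units)
compartment:
  resistivity_ohm_cm: 100.0
membrane:
  c_spec_uF_per_cm2: 1.0
  leak:
    g_mS_per_cm2: 0.025
    e_rev_mV: -65.0
channels:
  - name: NaHH
    builtin: hh_sodium
    g_single_pS: 20.0
    e_rev_mV: 50.0
    density_per_um2: 60.0          # 120 mS/cm^2 at 20 pS per channel
  - name: KHH
    builtin: hh_potassium
    g_single_pS: 20.0
    e_rev_mV: -77.0
    density_per_um2: 18.0          # 36 mS/cm^2
sim:
  dt_efield_ms: 0.005
  t_end_ms: 250.0
  v_init_mV: -65.0
  stim:
    i_nA: 0.1
    site: end0
  deterministic: true
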