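# Passive cable membrane (Rallpack 1 parameters, conventional units)
compartment:
  resistivity_ohm_cm: 100.0        # 1.0 Ohm m
membrane:
  c_spec_uF_per_cm2: 1.0           # 0.01 F/m^2
  leak:
    g_mS_per_cm2: 0.025            # 0.25 S/m^2  (Rm = 4 Ohm m^2)
    e_rev_mV: -65.0
sim:
  dt_efield_ms: 0.01
  t_end_ms: 250.0
  v_init_mV: -65.0
  stim:
    i_nA: 0.1
    site: end0
  deterministic: true
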