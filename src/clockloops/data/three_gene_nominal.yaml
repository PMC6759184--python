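# Nominal kinetic parameter set of the three-gene Per / Bmal1 / RevErb circuit.
params:
  d_p: 0.25    # 1/h
  d_b: 0.26    # 1/h
  d_r: 0.29    # 1/h
  v_p: 1.0     # a.u.
  v_b: 0.9     # a.u.
  v_r: 0.6     # a.u.
  k_p: 0.1     # a.u.
  k_b: 0.05    # a.u.
  k_r: 0.9     # a.u.
  c_p: 0.1     # a.u.
  c_r: 35.0    # a.u.  (Per -> RevErb repression constant; inter-loop coupling)
  b_p: 1.0     # fold  (Bmal1 -> Per activation; 1 = no direct feedback)
  b_r: 8.0     # fold
  delay_p: 8.333   # h
  delay_r: 1.52    # h
  delay_b: 3.652   # h
protocol:
  kind: none
  z: 0.0
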