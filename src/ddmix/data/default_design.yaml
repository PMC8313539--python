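# Default generative parameters of the diffusion / fast-guess mixture:
# across-subject mean estimates from the 5 (speed stress) x 5 (contrast)
# orientation-discrimination experiment the model was developed for.
# Speed index: 1 = extreme speed stress ... 5 = extreme accuracy stress.
# Contrast index: 1 = lowest contrast ... 5 = highest.
design:
  a: [0.063, 0.063, 0.072, 0.083, 0.106]       # boundary separation, by speed
  t_er: [0.356, 0.356, 0.382, 0.393, 0.414]    # mean nondecision time (s), by speed
  p_o: [0.735, 0.201, 0.0, 0.0, 0.0]           # fast-guess probability, by speed
  v: [0.108, 0.175, 0.283, 0.426, 0.546]       # drift rate, by contrast
  eta: 0.184    # SD of across-trial drift variability
  s_z: 0.037    # range of uniform starting-point variability
  s_t: 0.129    # range of uniform nondecision-time variability (s)
  mu_g: 0.262   # mean guess latency (s)
  s_g: 0.051    # SD of guess latency (s)
  s: 0.1        # within-trial noise SD (scaling constant)
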