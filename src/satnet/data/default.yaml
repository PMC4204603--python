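# Canonical experiment configuration for the speed-accuracy trade-off study.
# Units: time in ms, rates in Hz, currents in pA where marked (converted to
# nA internally) and nA otherwise.

model:
  a_hz_per_na: 270.0        # f-I gain
  b_hz: 108.0               # f-I offset
  d_s: 0.154                # f-I curvature
  gamma: 0.641              # rate-to-gating coupling
  tau_s_ms: 100.0           # gating (NMDA) time constant
  tau_noise_ms: 2.0         # noise-current correlation time
  j_self_na: 0.2609         # self-excitation
  j_cross_na: 0.0497        # cross-inhibition
  j_ext_na_per_hz: 0.00052  # external input scaling
  mu0_hz: 30.0              # stimulus reference rate

conditions:
  speed:    {i0_pa: 325.0, sigma_noise_na: 0.02}
  neutral:  {i0_pa: 321.0, sigma_noise_na: 0.02}
  accuracy: {i0_pa: 316.0, sigma_noise_na: 0.02}

schedule:
  t_prestim_ms: 2500.0
  t_stim_ms: 5000.0
  dt_ms: 0.1

experiment:
  coherences_pct: [0, 1, 2, 4, 8, 16, 32]
  n_trials: 1000
  theta_hz: 15.0
  sustain_steps: 1          # consecutive steps above theta required to choose
  trace_dt_ms: 10.0         # output resolution of stored rate traces
  master_seed: 12345

threshold_sweep:
  grid_min_hz: 9.0
  grid_max_hz: 21.0
  step_hz: 1.0
  probe_coherences_pct: [1, 32]

observer:
  criterion: 0.75           # AUC level for ideal-observer discrimination
  sustain_bins: 3           # consecutive bins the criterion must hold
  smooth_ms: 50.0           # moving-average window for last-intersection
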