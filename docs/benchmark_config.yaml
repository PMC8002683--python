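# Example configuration for `maxcalbench benchmark` / `maxcalbench simulate`.
# Desk-scale variant of the auto-activation benchmark: two replicates of
# twenty trajectories, each 48 recorded hours after a 12 h burn-in.
circuit: sgaa
models: [dm, cgm, maxcal]
simulation:
  t_end: 216000.0        # seconds, including the burn-in (12 h + 48 h)
  delta_t: 300.0         # frame interval, seconds
  n_trajectories: 20
  n_replicates: 2
  burn_in: 43200.0
  rng_seed: 7
# rates:                 # optional generator-rate overrides, e.g.
#   g_star: 0.4
# m: 16                  # fix the transition window instead of the heuristic
# nmax: 120              # fix the FSP bound instead of the data-driven choice
optimizer:
  n_starts: 5
  seed: 8
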