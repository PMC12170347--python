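# Full pipeline configuration. Any omitted key falls back to the defaults
# documented on SimConfig / PerturbConfig / PriorSpec / MCMCConfig /
# RegisterConfig.

sim:
  n_fine: 400
  n_per_l2: 4
  n_per_l3: 5
  n_per_l4: 5
  domain_size_km: 500.0
  pop_range: [30, 120]
  beta0_young: -6.319        # logit(0.0018)
  beta0_old: -5.254          # logit(0.0052)
  beta_ses: -0.05
  remoteness_effects: [-0.2, -0.1, 0.0, 0.1, 0.2]
  field_sd: 0.3
  field_range_km: 50.0
  mix_w: 0.9
  response_rate_range: [0.88, 0.95]
  seed: 1

perturb:
  d: 2
  noise_pmf: [0.1, 0.2, 0.4, 0.2, 0.1]
  tau: 2
  zero_fixed: true

priors:
  beta0_young: [0.0, 2.0]    # mean, sd on the logit scale
  beta0_old: [0.0, 2.0]
  beta_ses: [0.0, 2.0]
  gamma: [0.0, 2.0]
  log_sigma_u: [0.0, 1.0]
  log_rho: [3.912, 1.0]      # log(50 km)

mcmc:
  n_iter: 6000
  n_burn: 2000
  thin: 4
  n_chains: 2
  seed: 20210810

registers:
  capture_hospital: 0.999
  capture_community: 0.85
  seed: 1
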