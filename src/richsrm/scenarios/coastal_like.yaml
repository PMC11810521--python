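food_wealth_corr: -0.5
game_config:
  giving_coin: 1000
  giving_stake: 15000
  reduction_budget: 10000
  reduction_multiplier: 4
  taking_coin: 500
  token_cost: 1000
group_sizes:
  afro: 88
  embera: 28
income_base: 300000.0
income_log_sd: 0.6
income_ratio: 1.8
interethnic_marriage_rate: 0.02
kin_cluster_mean_size: 4.0
layer_params:
  friendship:
    fixed:
      alter:log_wealth: 0.2
      dyad:marriage: 2.0
      dyad:relatedness: 0.8
      intercept: -3.5
      parochial:afro: 1.2
      parochial:embera: 1.2
    rho_dd: 0.5
    rho_gr: 0.3
    sigma_d: 1.0
    sigma_r: 0.7
    sigma_s: 0.7
  giving:
    fixed:
      alter:log_wealth: -0.3
      parochial:afro: 0.8
      parochial:embera: 0.8
      self_intercept: 4.2
    rho_dd: 0.0
    rho_gr: 0.0
    sigma_d: 0.0
    sigma_r: 0.5
    sigma_s: 0.8
  reduction:
    fixed:
      alter:log_wealth: 0.3
      parochial:afro: 0.0
      parochial:embera: 0.0
      self_intercept: 6.5
    rho_dd: 0.0
    rho_gr: 0.0
    sigma_d: 0.0
    sigma_r: 0.5
    sigma_s: 1.0
  taking_leave:
    fixed:
      alter:food_insecurity: 0.3
      alter:log_wealth: -0.4
      intercept: 0.9
      parochial:afro: -0.5
      parochial:embera: 0.8
    rho_dd: 0.0
    rho_gr: 0.2
    sigma_d: 0.0
    sigma_r: 0.3
    sigma_s: 0.8
  transfer:
    fixed:
      alter:log_wealth: 0.2
      dyad:marriage: 2.0
      dyad:relatedness: 1.0
      intercept: -3.8
      parochial:afro: 0.0
      parochial:embera: 1.0
    rho_dd: 0.5
    rho_gr: 0.3
    sigma_d: 1.0
    sigma_r: 0.7
    sigma_s: 0.7
marriage_rate: 0.3
n_noncompleters: 22
name: coastal_like
report_recall: 0.8
site: coastal
wealth_base: 1000000.0
wealth_log_sd:
  afro: 0.9
  embera: 0.9
wealth_ratio: 3.7
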