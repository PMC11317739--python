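# Base-case model inputs for the CBA-vs-RFA cost-minimization model.
# Probabilities are per decision-tree procedure or per Markov year as named;
# costs are JPY (per event or per state-year). dsa_ranges hold the one-way
# sensitivity bounds (95% CIs where available, otherwise +/-20%).

start_age: 64.6
male_fraction: 0.67

# Decision-tree probabilities (shared by both strategies)
p_recur_first: 0.268
rr_recur_reablation: 1.61
p_reablate_2nd: 0.78
p_reablate_3rd: 0.37

# Repeat-procedure technology mix (probability the repeat procedure is RFA)
mix_2nd_rfa_after_rfa: 0.983
mix_2nd_rfa_after_cba: 0.964
mix_3rd_rfa_after_rfa: 0.979
mix_3rd_rfa_after_cba: 1.0

# Per-procedure serious adverse event probabilities
sae_probs_rfa:
  esophageal_injury: 0.005
  cardiac_tamponade: 0.010
  pv_stenosis: 0.010
  vascular: 0.020
  groin: 0.010
sae_probs_cba:
  esophageal_injury: 0.005
  cardiac_tamponade: 0.004
  pv_stenosis: 0.010
  phrenic_nerve_palsy: 0.010
  vascular: 0.020
  groin: 0.010

# Per-procedure ischemic stroke and procedural mortality
p_is_tree: 0.007
p_death_tree: 0.012

# Markov (annual) probabilities
p_recur_markov_y12: 0.077
p_recur_markov_later: 0.041
p_is_markov: 0.0024
p_is_death_28d: 0.073
p_is_death_1y_survivors: 0.127
p_death_post_is: 0.085

# Costs (JPY)
cost_proc_rfa: 2256516
cost_proc_cba: 2609223
sae_costs:
  esophageal_injury: 3261455
  cardiac_tamponade: 160598
  pv_stenosis: 1679342
  phrenic_nerve_palsy: 15230
  vascular: 107065
  groin: 107065
cost_is_nonfatal: 1127624
cost_is_fatal: 2429749
cost_state_af_pos: 172780
cost_state_af_neg: 36373
cost_state_post_is: 67486

discount_rate: 0.02
jpy_per_usd: 150

# One-way sensitivity bounds [low, high]
dsa_ranges:
  start_age: [63.9, 65.3]
  male_fraction: [0.638, 0.702]
  p_recur_first: [0.214, 0.322]
  rr_recur_reablation: [1.29, 1.93]
  p_reablate_2nd: [0.735, 0.825]
  p_reablate_3rd: [0.214, 0.526]
  mix_2nd_rfa_after_rfa: [0.978, 0.988]
  mix_2nd_rfa_after_cba: [0.952, 0.976]
  mix_3rd_rfa_after_rfa: [0.961, 0.997]
  sae_prob_esophageal_injury: [0.004, 0.006]
  sae_prob_cardiac_tamponade_rfa: [0.008, 0.012]
  sae_prob_cardiac_tamponade_cba: [0.003, 0.005]
  sae_prob_pv_stenosis: [0.008, 0.012]
  sae_prob_phrenic_nerve_palsy_cba: [0.008, 0.012]
  sae_prob_vascular: [0.016, 0.024]
  sae_prob_groin: [0.008, 0.012]
  p_is_tree: [0.006, 0.008]
  p_death_tree: [0.010, 0.014]
  p_recur_markov_y12: [0.062, 0.092]
  p_recur_markov_later: [0.033, 0.049]
  p_is_markov: [0.002, 0.003]
  p_is_death_28d: [0.058, 0.088]
  p_is_death_1y_survivors: [0.102, 0.152]
  p_death_post_is: [0.068, 0.102]
  cost_proc_rfa: [2247957, 2265075]
  cost_proc_cba: [2600718, 2617728]
  sae_cost_esophageal_injury: [2067117, 4455793]
  sae_cost_cardiac_tamponade: [157987, 163211]
  sae_cost_pv_stenosis: [1152122, 2206562]
  sae_cost_phrenic_nerve_palsy: [12184, 18276]
  sae_cost_vascular: [105325, 108807]
  sae_cost_groin: [105325, 108807]
  cost_is_nonfatal: [862765, 1392483]
  cost_is_fatal: [179672, 4679826]
  cost_state_af_pos: [138224, 207336]
  cost_state_af_neg: [33975, 38771]
  cost_state_post_is: [21579, 113393]
  discount_rate: [0.0, 0.04]
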