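# Example outbreak scenario: a Santa-Monica-shaped urban find.
# Three flies trapped in the first three days; countermeasures from day 21.
# Supply your own hourly station export (columns: timestamp, temp_c),
# gap-filled if needed (`medfoes` fills gaps from daily climatology).
name: santa_monica_like
first_find: "2009-10-28"
flies_found: 3
sex_ratio_female: 0.5
t_S: 21.0
runs: 10000
q: 0.95
r_var: 3.57
female_fraction: 0.5
gamma: 0.05
T_max: 35.0
N_m: 1000000
ddql_t_min: 9.825
ddql_k_generation: 399.855
ddql_generations: 3
age_structure: {e: 0.436, l: 0.403, p: 0.137, a_imm: 0.012, a_mat: 0.012}
ranges:
  M_star_e: [0.0198, 0.1200]
  M_star_l: [0.0068, 0.0946]
  M_star_p: [0.0016, 0.0465]
  M_star_a: [0.0245, 0.1340]
  S: [0.005, 0.050]
  T_min_e: [9.6, 12.5]
  K_e: [27.27, 33.80]
  T_min_l: [5.0, 10.8]
  K_l: [94.50, 186.78]
  T_min_p: [9.1, 13.8]
  K_p: [123.96, 169.49]
  T_min_a: [7.9, 9.9]
  K_a: [58.20, 105.71]
  r: [5.0, 35.0]
  r_red: [0.5, 1.0]
  trap_sensitivity: [0.02, 0.03]
temperature:
  path: station_hourly.csv
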