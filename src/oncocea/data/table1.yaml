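# Published parameter set: four first-line PD-1/PD-L1 strategies for
# high-PD-L1 NSCLC from the Chinese healthcare perspective (2020 USD).
# The atezolizumab strategy carries the directly fitted Weibull OS/PFS
# curves; the other strategies' hazard ratios vs atezolizumab are the
# fixed-effects NMA contrasts computed from the packaged evidence table
# five_trials_high_pdl1.csv (their dsa ranges are the NMA 95% CIs).
reference_strategy: atezolizumab
wtp_threshold: 32517.0        # 3x China 2020 per-capita GDP, $/QALY
discount_rate: 0.05           # per year, costs and QALYs alike
cycle_length_days: 21
termination_death_fraction: 0.99
os_curve: {scale: 0.055227, shape: 0.724424}   # months
pfs_curve: {scale: 0.119257, shape: 0.701234}
utilities:
  pfd: 0.804
  pd: 0.321
costs:                         # money per cycle except one-off uses in-model
  inpatient: 55.6
  pd_treatment: 854.1
  best_supportive_care: 337.5
  terminal: 2627.8
  ae_management: 362.2
strategies:
  - name: atezolizumab
    drug_cost_per_cycle: 4930.3
    sae_rate: 0.3007
    hr_os: 1.0
    hr_pfs: 1.0
  - name: nivolumab
    drug_cost_per_cycle: 4171.2
    sae_rate: 0.176
    hr_os: 1.525424
    hr_pfs: 1.698413
  - name: pembrolizumab
    drug_cost_per_cycle: 5386.7
    sae_rate: 0.1949
    hr_os: 1.133329
    hr_pfs: 1.117012
  - name: durvalumab
    drug_cost_per_cycle: 6117.5
    sae_rate: 0.149
    hr_os: 1.288136
    hr_pfs: 1.380952
dsa_ranges:
  costs.inpatient: [41.7, 69.4]
  costs.pd_treatment: [706.5, 992.4]
  costs.best_supportive_care: [158.7, 793.7]
  costs.terminal: [2291.8, 2966.6]
  costs.ae_management: [271.6, 452.7]
  utilities.pfd: [0.643, 0.965]
  utilities.pd: [0.257, 0.385]
  discount_rate: [0.0, 0.08]
  strategies.nivolumab.hr_os: [0.891658, 2.609652]
  strategies.nivolumab.hr_pfs: [1.060950, 2.718888]
  strategies.pembrolizumab.hr_os: [0.729861, 1.759836]
  strategies.pembrolizumab.hr_pfs: [0.768918, 1.622689]
  strategies.durvalumab.hr_os: [0.783351, 2.118200]
  strategies.durvalumab.hr_pfs: [0.824948, 2.311696]
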