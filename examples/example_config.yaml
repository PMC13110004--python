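# Illustrative four-subgroup MRD simulation.
# Response categories (CR/PR/SD/PD) get progressively shallower MRD
# responses, higher relapse probabilities and earlier relapse onsets.
# These values are illustrative defaults, not estimates from any study.
time_unit: months

subgroups:
  - name: CR      # complete responders: deep plateau, rare late relapse
    n: 60
    beta0_meanlog: -2.0
    beta0_sdlog: 0.5
    beta1_meanlog: -9.0
    beta1_sdlog: 0.7
    te: 6.0
    relapse_prob: 0.15
    relapse_mean: 30.0
    relapse_sd: 5.0
    beta2: 0.25
    sigma: 0.02
  - name: PR
    n: 50
    beta0_meanlog: -1.5
    beta0_sdlog: 0.5
    beta1_meanlog: -6.0
    beta1_sdlog: 0.7
    te: 6.0
    relapse_prob: 0.4
    relapse_mean: 24.0
    relapse_sd: 5.0
    beta2: 0.25
    sigma: 0.02
  - name: SD
    n: 40
    beta0_meanlog: -1.0
    beta0_sdlog: 0.5
    beta1_meanlog: -3.5
    beta1_sdlog: 0.7
    te: 6.0
    relapse_prob: 0.7
    relapse_mean: 18.0
    relapse_sd: 5.0
    beta2: 0.25
    sigma: 0.02
  - name: PD      # progressive disease: shallow response, near-certain relapse
    n: 30
    beta0_meanlog: -0.7
    beta0_sdlog: 0.5
    beta1_meanlog: -1.5
    beta1_sdlog: 0.7
    te: 6.0
    relapse_prob: 0.95
    relapse_mean: 10.0
    relapse_sd: 5.0
    beta2: 0.25
    sigma: 0.02

hazard:
  baseline_family: exponential
  baseline_params: {rate: 0.02}   # events per month for the reference subject
  gamma: [0.3]                    # log-hazard ratio for tp53 (below)
  alpha1: 0.4                     # risk per log10 unit of current MRD
  alpha2: 0.0
  alpha3: 0.0
  link_scale: log10
  t_max: 48.0                     # administrative censoring (months)
  dropout_rate: 0.0

schedule:
  mode: regular
  interval: 3.0                   # quarterly assessments
  horizon: 48.0
  jitter_sd: 0.2
  miss_prob: 0.05

covariates:
  - name: tp53
    kind: binary
    params: {p: 0.35}

noise_mode: additive
lod: 1.0e-4                       # assay limit of detection
censor_at_lod: false

colormaps:
  tp53: ["#1b9e77", "#d95f02"]
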