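# Demo pipeline configuration: four synthetic development cohorts drawn from
# the pooled three-predictor logistic model with between-study heterogeneity,
# a simulated external validation register, and the decision analysis.
seed: 20210525
out_dir: results/demo
simulate:
  outcome: logistic
  sigma_u: 0.3
  missing_rate: 0.005
develop:
  n_bootstrap: 50
validate:
  n: 3324
decision:
  grid: {lo: 0.005, hi: 0.30, step: 0.005}
  clinical_range: [0.03, 0.15]
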