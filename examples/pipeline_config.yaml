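# Example configuration for `flux-pipeline run --config pipeline_config.yaml`.
# Omitted keys fall back to the defaults in mfa13.pipeline.PipelineConfig.
outdir: pipeline_out
seed: 1
model: toy            # or a path to an FTBL-subset file
energy_model: toy_energy
reference: reference
mc_draws: 100
n_starts: 5
mid_sd: 0.01
od_cv: 0.03
conc_cv: 0.05
inoculum_fraction: 0.025
strains:              # strain -> {reaction: multiplicative edit}
  ppp_up:
    scramble: 2.0
  pdc_up:
    pdc: 2.0
pathway_sets:
  UG: [upt, cond]
  PPP: [cleave, scramble]
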