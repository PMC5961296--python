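# Bundled fixture run configuration: a small synthetic multi-study cohort
# whose covariate prevalences approximate the pooled HEU population
# (LBW ~12%, never breastfed ~30%, maternal ARV mix ~23/61/12/4%,
# CD4>=350 ~58%, ~80% of studies African), with heterogeneous baseline
# hazards across studies (gamma frailty, variance 0.25).
#
# Sized for a quick end-to-end run; scale n_studies/children_per_study up
# (e.g. 20 x 960) to emulate the full pooled cohort.
seed: 20170701
simulate:
  n_studies: 8
  children_per_study: 250
  n_asia_studies: 2
  frailty_variance: 0.25
aaf_horizons: [183, 365, 730]
aaf_bootstrap: 0          # point estimates only; set >= 2 for bootstrap CIs
run_selection: true
run_weaning_td: true
run_joint_bf_art: true
run_aaf: true
output_dir: heusurv_out
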