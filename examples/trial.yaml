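# Example run configuration: a 2-arm trial at the study's sample sizes.
seed: 1
n_app: 104
n_usual: 105
detail: outcomes        # "events" runs the decision engine in the loop
out_dir: out

engine:
  fence_radius_m: 100
  min_reports_for_fence: 2
  min_dwell_minutes: 5
  redecision_interval_hours: 3
  active_window: "08:00-21:30"
  stage2_duration_days: 28
  monthly_decay_factor: 0.5
  support_stop_months: 3
  trigger_threshold: 2

engagement:
  install_prob: 0.75
  engagement_median_days: 10
  followup_prob_6m: 0.77
  followup_prob_6w: 0.71
  saliva_return_prob_by_arm:
    app: 0.52
    usual_care: 0.19
  misreport_prob: 0.10

simulation:
  cigarettes_mean: 15.4
  cigarettes_sd: 7.1
  low_ses_prob: 0.292
  horizon_days: 180
  baseline_lapse_hazard: 0.012
  message_effect_multiplier: 0.5
  relapse_given_lapse: 0.3
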