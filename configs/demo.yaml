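# End-to-end demo: a small synthetic cohort through every stage.
# Runs in about a minute on one CPU; rerunning with the same seed
# reproduces every output byte-for-byte (see manifest.json checksums).
seed: 20200301
stages: [simulate, score, associate, trajectory, forecast, respond-score, enrich]
params:
  simulate:
    n_users: 30
    n_days: 100
    post_rate: 3.0
    mention_threshold: 0.6
    mention_min_day: 55
    response_prob: 0.6
    response_drift: -0.03
    survey_every: 21
  associate:
    windows: "1:21"
    min_posts: 0
    threshold_si: 1
    auc_window: 14
    n_perm: 2000
  trajectory:
    mode: all_days_between
    thresholds: "10:100:5"
  forecast:
    eval_days: 5
  respond-score:
    window_hours: 72
    horizon: 21
    threshold: corpus_mean
    min_history: 100
  enrich:
    min_count: 3
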