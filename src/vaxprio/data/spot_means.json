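{
  "note": "Per-criterion collective mean ranks reported in the study narrative. Not recomputable from this package: the raw workshop ballots were not deposited. These values serve only as approximation targets for the synthetic-ballot calibrator.",
  "n_vaccines": 6,
  "spot_means": [
    {"criterion": "effectiveness", "vaccine": "hpv", "mean_rank": 1.1},
    {"criterion": "waning", "vaccine": "hpv", "mean_rank": 1.3},
    {"criterion": "serotype_coverage", "vaccine": "hpv", "mean_rank": 2.7},
    {"criterion": "amr_impact", "vaccine": "hpv", "mean_rank": 5.7},
    {"criterion": "amr_impact", "vaccine": "flu_hr", "mean_rank": 1.5},
    {"criterion": "mortality", "vaccine": "pcv_hr", "mean_rank": 1.4},
    {"criterion": "mortality", "vaccine": "rsv", "mean_rank": 2.4},
    {"criterion": "incidence", "vaccine": "flu_hr", "mean_rank": 2.5},
    {"criterion": "incidence", "vaccine": "varicella", "mean_rank": 2.6},
    {"criterion": "schedule_fit", "vaccine": "varicella", "mean_rank": 2.4},
    {"criterion": "schedule_fit", "vaccine": "hpv", "mean_rank": 2.5}
  ]
}
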