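# Synthetic-data generator preset: the default study conditions.
# Cohort A (1,333) shares 272 dual-enrolled persons with cohort B (2,369),
# so deterministic linkage retains 3,430 unique persons; the self-report
# instrument is completed by ~549 of the 1,061 non-duplicated cohort-A
# persons. Instrument operating characteristics: self-report 0.95/0.84,
# administrative coding 0.629/0.938.
true_prevalence: 0.59
n_cohort_a: 1333
n_cohort_b: 2369
duplicate_rate: 0.20405101275318831   # 272/1333
instrument_completion_rate: 0.5174363807728558  # 549/1061
selfreport_sens: 0.95
selfreport_spec: 0.84
admin_sens: 0.629
admin_spec: 0.938
lookback_years: 5
enrollment_window: ["2011-06-01", "2021-04-30"]
censor_rate: 0.024198250728862973  # 83/3430
seed: 123
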