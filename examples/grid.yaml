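# Example grid for `simulate-grid --config examples/grid.yaml --out results/grid`
# List values expand into the Cartesian product of scenarios.
design: [cohort, case_cohort]
n_cohort: [10000]
sampling_fraction: [0.10]   # used by the case_cohort design only
raf: [0.10]
hr: [1.1, 1.2, 1.5, 2.0]
incidence: [0.05, 0.10, 0.15]
censoring: [complete, survey, random]
n_replicates: 1000
seed: 20170503
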