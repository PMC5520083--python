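"""Run a small power/bias grid and print the summary table.

Each grid cell simulates replicate cohorts, fits both models to every
replicate, and reports mean bias, mean SE and power per model plus the
difference in power (Cox minus logistic). Replicates are reduced here so the
example runs in about a minute; the power columns are therefore noisy.
"""

from survgwas import GridConfig, run_grid

config = GridConfig(
    design=["cohort"],
    n_cohort=[10_000],
    raf=[0.10],
    hr=[1.2, 1.5],
    incidence=[0.10],
    censoring=["complete", "random"],
    n_replicates=200,
    seed=3,
)
frame, failures = run_grid(config)
cols = [
    "censoring", "true_hr", "cox_mean_bias", "cox_power",
    "logistic_mean_bias", "logistic_power", "power_diff",
]
print(frame[cols].round(4).to_string(index=False))
# Cox bias hovers near zero everywhere; the logistic bias is positive and
# grows with the hazard ratio; the Cox power advantage appears under random
# censoring but not under complete follow-up.
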