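"""Parameter recovery on simulated virtual trials.

Simulates replicated virtual studies with the same schedules, cohort sizes
and chemotherapy categories as the real tables, with survivor counts drawn
binomially from the model's true survival, then re-runs the full staged fit
on each replicate. Reports how often each generating parameter is recovered
within two standard errors -- the end-to-end calibration of the pipeline.

Uses 50 replicates for a quick run; the packaged tests use 200.
"""

from chemorad import parameter_recovery_study, recovery_rates

study = parameter_recovery_study(n_replicates=50, seed=2024)
rates = recovery_rates(study, k=2.0)

truth = study.attrs["truth"]
print("generating values:", truth)
print("\nfraction of replicates within 2 SE of truth:")
print(rates.round(3).to_string())
print(
    "\nRates near 0.95 mean the staged fit plus its propagated standard "
    "errors are well calibrated under the model's own sampling assumptions."
)
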