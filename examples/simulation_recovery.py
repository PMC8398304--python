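"""Parameter recovery on synthetic two-sample studies.

Generates exposure and outcome cohorts with a known causal effect, runs the
whole pipeline (harmonize, Wald ratio with second-order SE) on each
replicate, and checks bias and confidence-interval coverage — including a
scenario that deliberately violates the exclusion restriction.
"""

from snpmr import SimScenario, marginal_log_or_per_allele, run_recovery_experiment

null = run_recovery_experiment(SimScenario(seed=1), 200)
print(f"null (theta=0):       mean estimate {null.mean_estimate:+.5f}, 95% CI coverage {null.coverage:.2f}")

effect = SimScenario(seed=2, theta=0.005, n_cases=4000, n_controls=4000)
truth = marginal_log_or_per_allele(effect) / effect.beta_gx
summary = run_recovery_experiment(effect, 200)
print(
    f"effect (theta=0.005): mean estimate {summary.mean_estimate:.5f}, marginal truth {truth:.5f}, "
    f"coverage {summary.coverage:.2f}"
)

pleiotropy = run_recovery_experiment(
    SimScenario(seed=3, pleiotropy_beta=0.1, n_cases=3000, n_controls=3000), 200
)
print(f"pleiotropic null:     mean estimate {pleiotropy.mean_estimate:+.5f}, coverage {pleiotropy.coverage:.2f}")

print(
    "\nUnder valid assumptions coverage sits near 0.95 and the mean tracks "
    "the marginal (non-collapsible) truth, slightly below theta itself. With "
    "a direct variant->outcome path of 0.1 log-odds per allele the estimator "
    "is biased (~0.1/17.1 per g/day) and coverage collapses: the exclusion "
    "restriction is not testable from one instrument, only simulatable."
)
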