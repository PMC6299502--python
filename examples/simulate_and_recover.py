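"""Parameter recovery on simulated MNAR trials.

Simulates four-arm trials (300 subjects/arm, 25% true abstinence) where
tobacco users miss the survey at three times the odds of abstainers
(true OR1 = 3) and unconfirmable self-reported abstainers miss the urine
test at three times the odds of confirmable ones (true OR2 = 3).  Two
analyses of the same replicates are compared against the latent truth:
imputation at the true odds ratios, and missing = smoking (OR = inf).
"""

import math

from cessmiss import SensitivityParams, fixture_like_scenario, recovery_experiment

scenario = fixture_like_scenario(true_or1=3.0, true_or2=3.0, seed=7)
cols = ["contrast", "pool", "mean_truth", "mean_estimate", "mean_bias", "se_bias"]

for label, params in [
    ("analysis at the true ORs (matched)", SensitivityParams(or1=3.0, or2=3.0)),
    ("missing = smoking analysis", SensitivityParams(or1=math.inf, or2=math.inf)),
]:
    res = recovery_experiment(scenario, params, n_reps=50)
    verified = res[res.outcome == "urine_verified"]
    print(f"\n{label} - pooled urine-verified abstinence rates, 50 replicates")
    print(verified[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))

print(
    "\nMatched imputation leaves bias within Monte-Carlo error of zero; "
    "assuming missing = smoking when the true association is moderate "
    "systematically underestimates the abstinence rate."
)
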