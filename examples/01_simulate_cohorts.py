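"""Simulate a development/validation cohort pair and inspect treatment patterns.

The development cohort is treatment-naive; in the validation cohort
high-risk individuals are preferentially treated and treatment halves
their outcome odds, so observed incidence falls below untreated incidence.
"""

from treatval import RngState, builtin_scenario, generate_validation_pair

cfg = builtin_scenario("scenario_1")
dev, val = generate_validation_pair(cfg, RngState(seed=42, label=cfg.id))

print(f"scenario {cfg.id}: n_dev={len(dev)}, n_val={len(val)}")
print(f"development treated fraction: {dev.treated.mean():.3f} (treatment-naive)")
print(f"validation  treated fraction: {val.treated.mean():.3f} (target {cfg.target_treated_fraction})")
tr, un = val.treated == 1, val.treated == 0
print(f"mean untreated risk | treated:   {val.risk_untreated[tr].mean():.3f}")
print(f"mean untreated risk | untreated: {val.risk_untreated[un].mean():.3f}")
print(f"validation incidence had no one been treated: {val.y_untreated.mean():.3f}")
print(f"validation incidence actually observed:       {val.y_observed.mean():.3f}")
print()
print("Treated individuals are riskier on average (allocation follows risk),")
print("and effective treatment lowers the observed event rate below the")
print("counterfactual untreated rate the prognostic model is meant to predict.")
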