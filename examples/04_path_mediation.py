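"""Fit the mediation path model by FIML and decompose the NWC effect.

The joint model regresses the age-4 trait on NWC and confounders, and the
age-7 trait on those plus the age-4 trait (the tracking edge).  The NWC
effect on the age-7 trait splits into a direct part and an indirect part
through the age-4 trait.
"""

from nadirpath import simulate_path_cohort, build_model, fit, bootstrap_ci

data = simulate_path_cohort("waist", 312, seed=7)  # tracking 0.725, null NWC effects
spec = build_model("waist", "joint")
result = fit(spec, data)

coefs = result.table[result.table["role"] == "coef"]
print(coefs[["child", "parent", "label", "estimate", "se"]].to_string(index=False))
print(f"\nCFI {result.cfi:.3f}  TLI {result.tli:.3f}  RMSEA {result.rmsea:.3f}")
print("\neffect decomposition (NWC -> age-7 waist):")
print(result.effects.to_string(index=False))

ci = bootstrap_ci(build_model("waist", "model2_age7"), data, n_boot=200, seed=8)
row = ci[ci["label"] == "b5"].iloc[0]
print(f"\ntracking coefficient b5 = {row['estimate']:.3f} "
      f"(bootstrap 95% CI {row['ci_lo']:.3f}; {row['ci_hi']:.3f})")
# With null generating NWC effects the direct/indirect/total estimates sit
# near zero, while the tracking edge is recovered near its true 0.725.
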