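"""Fit the multivariable ΔRCSA regression on a synthetic cohort.

Generates a 90-patient two-arm cohort in which the open (TLIF) approach
lowers Average-ΔRCSA by 0.160 and smoking by 0.105, then fits the full
covariate-adjusted OLS and prints each coefficient with its collinearity
diagnostics, the way a clinical regression table is reported.
"""

from paramuscle import CohortSpec, generate_cohort, multivariable_ols
from paramuscle.pipeline import _encode_regression_design

df = generate_cohort(CohortSpec(seed=7))
res = multivariable_ols(df["avg_delta_rcsa"].to_numpy(), _encode_regression_design(df))

print(f"n = {res.n}, R² = {res.r_squared:.3f}")
print(f"{'covariate':>18s} {'beta':>8s} {'std.beta':>9s} {'t':>7s} {'p':>7s} {'VIF':>6s}")
for row in res.coefficients:
    if row.name == "const":
        continue
    print(
        f"{row.name:>18s} {row.effect['beta']:+8.3f} "
        f"{row.effect['standardized_beta']:+9.3f} {row.statistic:+7.2f} "
        f"{row.p_value:7.4f} {row.diagnostics['vif']:6.2f}"
    )
# The group and smoking rows should be strongly significant (p < 0.01)
# with betas near the generating -0.160 and -0.105; every other covariate
# has no generating effect, and all VIFs stay well below 5.
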