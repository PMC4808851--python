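"""Develop and cross-validate a population-specific FFM equation.

Splits a synthetic cohort 2:1 into development and cross-validation
groups, fits a new model by bidirectional stepwise OLS over the standard
candidate pool, and reports agreement with the DXA reference in both
groups and the total sample.
"""

import biaffm

cohort = biaffm.generate(biaffm.default_config(), seed=11)
result = biaffm.develop_and_validate(cohort, dev_fraction=2 / 3, seed=3)

model = result.model
terms = " + ".join(
    f"{model.coefficients[name]:.3f}*{name}" for name in model.selected_predictors
)
print(f"fitted:  FFM = {terms} + {model.coefficients['intercept']:.3f}")
print(f"development fit: adj R^2 = {model.r2_adj:.2f}, SEE = {model.see:.1f} kg, "
      f"residual normality p = {model.residual_normality_p:.2f}")
print(f"groups: DG n={result.split.sizes[0]}, CVG n={result.split.sizes[1]}\n")

table = biaffm.reports_to_frame(
    [result.dg_report, result.cvg_report, result.total_report], rounded=True
)
cols = ["equation_id", "mean_pred", "mean_diff", "pct_diff", "paired_p",
        "ccc", "precision_rho", "accuracy_cb", "r2_adj", "see", "pure_error"]
print(table[cols].to_string(index=False))

print("\nThe development-group mean difference is exactly 0.0 (OLS residuals "
      "sum to zero on the fitting sample); the cross-validation row is the "
      "honest assessment — a paired p above 0.05 means no detectable mean "
      "bias on held-out subjects.")
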