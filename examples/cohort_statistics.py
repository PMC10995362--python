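"""Generate the synthetic three-group cohort and run the statistics stage.

The cohort mirrors the study scaffold: 81 eyes in emmetropia (EM),
low/moderate myopia (LM/MM), and simple high myopia (SHM) groups, with
axial-length-coupled imaging and CSF outcomes.  The stage runs the one-way
ANOVA group comparison, the sex chi-square, and the univariate ->
multivariate regression screen for AULCSF.
"""

from myovis import compare_groups, correlate, regression_screen, sex_distribution_test
from myovis.synthetic import CohortSpec, gen_cohort

df = gen_cohort(CohortSpec(seed=0))
print(f"cohort: {len(df)} eyes; groups {df['group'].value_counts().to_dict()}")

cmp_res = compare_groups(df, "aulcsf")
means = ", ".join(f"{g} {m:.2f}" for g, m in cmp_res.group_means.items())
print(f"AULCSF by group: {means}  (ANOVA p = {cmp_res.p_overall:.4f})")

chi2, p = sex_distribution_test(df)
print(f"sex distribution chi-square = {chi2:.2f}, p = {p:.3f}")

r, p = correlate(df, "al_mm", "cone_density_outer")
print(f"AL vs outer cone density: r = {r:.3f}, p = {p:.2g}")

screen = regression_screen(df, "aulcsf",
                           ["al_mm", "cone_density_outer", "ct_um", "cvi", "is_um"])
print(f"univariate screen passed: {screen.selected}")
if screen.final is not None:
    for pred in screen.final.predictors:
        print(f"  final model: {pred} beta={screen.final.beta[pred]:.4g} "
              f"std beta={screen.final.beta_standardized[pred]:.3f} "
              f"p={screen.final.p_values[pred]:.3g}")
print()
print("Predictors univariately associated with AULCSF (p < 0.05) enter the")
print("multivariable model, then backward elimination prunes to p < 0.05.")
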