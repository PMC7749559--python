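"""Two-way factorial ANOVA with Tukey-Kramer post hoc on simulated turnover.

Runs the full generator -> estimator path, then tests genotype, tumour and
interaction effects on the myofibrillar degradation constants.
"""

from heavywater import (
    NoiseModel,
    default_groups,
    estimate_cohort_turnover,
    simulate_cohort,
    tukey_kramer,
    two_way_anova,
)

dataset = simulate_cohort(default_groups(), noise=NoiseModel(seed=2))
est = estimate_cohort_turnover(dataset)
myo = est[(est.fraction == "myofibrillar") & est.valid]

res = two_way_anova(myo.kdeg, myo.genotype, myo.treatment,
                    factor_a="genotype", factor_b="treatment")
print(res.to_frame().round(6).to_string(index=False))

for comp in tukey_kramer(res, alpha=0.05):
    star = "*" if comp.significant else " "
    print(f"{star} {'-'.join(comp.group_i):>13} vs {'-'.join(comp.group_j):<13} "
          f"diff = {comp.mean_difference:+.4f}  q = {comp.q:6.2f}  p = {comp.p:.2e}")
# Significant genotype and tumour main effects (and their interaction) mirror
# the planted pattern: tumour-bearing Sod1KO animals degrade myofibrillar
# protein fastest.
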