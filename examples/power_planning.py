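"""Reproduce the study's power planning around the SESOI of dz = 0.5.

A 0.1 difference in mean MM1 between styles, at an assumed sd of 0.2 and
within-rater correlation 0.5, is a standardized paired effect of dz = 0.5.
With alpha split over three planned comparisons, 60 raters give 95%
one-sided power; the Wilcoxon fallback loses little; and the TOST
equivalence test at bounds of +-0.5 dz has ~0.97 power under a true null.
"""

from sharedtaste import (
    bonferroni_alpha,
    dz_from_means,
    power_paired_t,
    power_tost_paired,
    power_wilcoxon_sim,
    solve_n_paired_t,
)

dz = dz_from_means(mean1=0.44, mean2=0.34, sd1=0.2, sd2=0.2, r_within=0.5)
alpha = bonferroni_alpha(0.05, 3)
print(f"SESOI: dz = {dz:.3f}  (0.1 raw MM1 at sd 0.2, r = 0.5)")
print(f"per-comparison alpha for 3 contrasts: {alpha:.3f}")

print(f"paired t power, n=60, one-sided: {power_paired_t(60, dz, alpha, 'one'):.3f}")
print(f"smallest n for 95% power:        {solve_n_paired_t(dz, alpha, 0.95, 'one')}")

w_power, w_se = power_wilcoxon_sim(
    60, raw_diff=0.1, sd=0.2, alpha=alpha, tails="two", n_sims=10_000, seed=1
)
print(f"Wilcoxon fallback power (sim):   {w_power:.3f} (MC SE {w_se:.3f})")

print(f"TOST equivalence power, n=60:    {power_tost_paired(60, 0.5, 0.05):.3f}")
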