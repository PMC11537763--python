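"""Generate a synthetic rating study and compare agreement measures.

Builds a full study-sized dataset (62 raters x 330 stimuli x 2 sessions)
under the default crossed variance-component model, then computes every
interrater agreement measure per vocalization style.  Correlational
measures (MM1, Kendall's W) sit well above the absolute-agreement
measures (Krippendorff's alpha, ICC) because raters use the 1-9 scale
with different personal offsets.
"""

from sharedtaste import (
    SyntheticConfig,
    average_sessions,
    generate_ratings,
    icc_2_1,
    kendalls_w,
    krippendorff_alpha,
    mm1,
    mm1_ci,
    slice_by_style,
)

table, truth = generate_ratings(SyntheticConfig(seed=1))
matrix = average_sessions(table)

print(f"{'style':>8}  {'MM1':>6}  {'95% CI':>16}  {'alpha_K':>7}  {'ICC':>6}  {'W':>6}")
for style in table.styles:
    sliced = slice_by_style(matrix, style, table.meta)
    res = mm1(sliced)
    low, high = mm1_ci(res)
    print(
        f"{style:>8}  {res.estimate:6.3f}  [{low:6.3f}, {high:6.3f}]  "
        f"{krippendorff_alpha(sliced).estimate:7.3f}  "
        f"{icc_2_1(sliced).estimate:6.3f}  {kendalls_w(sliced).estimate:6.3f}"
    )
print(
    "\nMM1 near the configured asymptotic value "
    f"({truth.implied_mm1['lullaby']:.3f}) in every style; the absolute "
    "measures are pulled down by rater bias (sigma2_rater > 0)."
)
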