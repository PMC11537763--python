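"""Decompose rating variance into shared and private taste.

Fits the crossed rater x stimulus x session variance-component model to
one style slice of a synthetic dataset and derives the beholder indices:
bi1, the private share of stable taste variance ignoring rater bias, and
bi2, which counts rater bias as private.  Their complements are the
shared-taste fractions.
"""

from sharedtaste import (
    SyntheticConfig,
    beholder_indices,
    estimate_variance_components,
    generate_ratings,
    shared_taste_complement,
)

config = SyntheticConfig(seed=1)
table, truth = generate_ratings(config)

for style in ("lullaby", "AD"):
    vc = estimate_variance_components(table.subset_style(style))
    bi = beholder_indices(vc)
    shared1, shared2 = shared_taste_complement(bi)
    print(f"{style}:")
    for cluster, value in vc.as_dict().items():
        print(f"  sigma2_{cluster:<11} = {value:6.3f}")
    print(
        f"  bi1 = {bi.bi1:.2f} (true {truth.implied_bi1[style]:.2f}), "
        f"bi2 = {bi.bi2:.2f} (true {truth.implied_bi2[style]:.2f})"
    )
    print(f"  shared taste: 1-bi1 = {shared1:.2f}, 1-bi2 = {shared2:.2f}\n")

print(
    "Private taste (the rater x stimulus cluster) dominates the stable\n"
    "variance, as configured: taste is mostly idiosyncratic."
)
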