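# sharedtaste

Shared vs. idiosyncratic taste in rating experiments: interrater
agreement statistics, variance-component decomposition, equivalence
testing and power planning for crossed rating designs.

## The problem

When many people rate the same set of stimuli — here, vocal performances
(lullaby, pop and operatic singing; adult- and infant-directed speech)
rated for liking on a 1–9 scale — how much of their taste is *shared*
(driven by the stimuli) and how much is *private* (idiosyncratic to each
rater)? The package implements the full analysis toolkit for this
question on a crossed rater × stimulus × session design:

- **MM1 ("mean-minus-one") agreement.** For each rater *i*, the Pearson
  correlation *r*ᵢ between their ratings and the mean ratings of all
  other raters; pooled as MM1 = tanh( mean( atanh *r*ᵢ ) ), i.e. averaged
  on the Fisher-*z* scale. Normal-theory CIs come from the spread of the
  individual *z*ᵢ.
- **Variance components and beholder indices.** The crossed model
  *y*ᵣᵢₜ = μ + aᵣ + bᵢ + cₜ + dᵣᵢ + eᵣₜ + εᵣᵢₜ is fitted (closed-form
  expected mean squares on balanced data, average-information REML
  otherwise). From the fitted σ², the beholder indices
  bi₁ = σ²ᵣᵢ / (σ²ᵢ + σ²ᵣᵢ) and
  bi₂ = (σ²ᵣ + σ²ᵣᵢ) / (σ²ᵢ + σ²ᵣ + σ²ᵣᵢ)
  give the private share of the stable, non-residual variance; 1 − bi is
  shared taste.
- **Alternative agreement measures** on the same matrix: Krippendorff's
  α (coincidence-matrix form, interval/ordinal/nominal metrics, with a
  bootstrap CI), ICC(2,1), Kendall's W with ties correction, Cronbach's α
  (flagged as a consistency, not agreement, coefficient), and per-rater
  test–retest reliability.
- **Registered inference.** One-tailed paired *t*-tests with Holm
  correction for directional predictions, TOST equivalence tests around a
  smallest effect size of interest (SESOI, *d*z = 0.5), a Wilcoxon
  signed-rank fallback, and the corresponding noncentral-*t* and
  simulation-based power computations.
- **Interstyle consistency.** MM1 reused with the five styles as "raters"
  judging the 22 performers; consistency is called high only when the CI
  lower bound reaches 0.8.
- **A synthetic-data generator** reproducing the full study design
  (62 raters × 22 singers × 3 melodies × 5 styles × 2 sessions) with
  known ground-truth variance components, for calibration and parameter
  recovery.

## Worked example

`examples/simulate_and_agree.py` generates a study-sized dataset and
compares the agreement measures per style:

```
   style     MM1            95% CI  alpha_K     ICC       W
      AD   0.517  [ 0.498,  0.537]    0.142   0.150   0.271
      ID   0.421  [ 0.394,  0.448]    0.095   0.103   0.195
 lullaby   0.503  [ 0.483,  0.523]    0.127   0.135   0.267
   opera   0.433  [ 0.408,  0.459]    0.089   0.098   0.206
     pop   0.418  [ 0.393,  0.442]    0.082   0.091   0.186
```

MM1 sits near 0.5 — raters agree moderately on which voices they like —
while the absolute-agreement measures (α, ICC) are far lower because
raters occupy different regions of the 1–9 scale (rater bias variance).
`examples/variance_components.py` decomposes the same data: bi₁ ≈ 0.61,
i.e. about 60% of the stable meaningful variance is private taste, and
`examples/power_planning.py` reproduces the planning arithmetic
(SESOI *d*z = 0.5; 95% one-tailed power at n = 60 and α = 0.017; Wilcoxon
fallback power ≈ 0.9; TOST power ≈ 0.97). `examples/full_report.py` runs
the whole registered pipeline and writes a JSON report.

The other examples and the `run_full_analysis` pipeline follow the same
pattern: build or load a `RatingTable`, slice by style, compute.

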