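# Methods

## The rating model

All analyses assume a crossed design: every rater rates every stimulus in
every session, with ratings on a 1–9 Likert scale. Within one
vocalization style the generative model is

    y_rit = mu_style + a_r + b_i + c_t + d_ri + e_rt + eps_rit

with independent zero-mean Gaussian effects: rater bias `a` (scale use),
stimulus effect `b` (shared taste), session effect `c`, rater × stimulus
interaction `d` (private taste), rater × session interaction `e`
(day-to-day drift in scale use), and residual noise `eps`. The
stimulus × session cluster is omitted: with one observation per
(rater, stimulus, session) cell it is confounded with the residual, and
it carries no substantive interpretation here.

Under this model the asymptotic (many-rater, session-averaged) individual
MM1 correlation is sqrt(sigma2_item / (sigma2_item + sigma2_rater_item +
sigma2_res / n_sessions)), and the test–retest correlation is
(sigma2_item + sigma2_rater_item) / (that sum + sigma2_res within one
session). These closed forms are used as recovery oracles in the tests.

## Agreement measures

**MM1.** Each rater's ratings are correlated with the column-mean of all
other raters; the correlations are pooled on the Fisher-z scale and
back-transformed. Before `atanh`, correlations are clamped to
±(1 − 1e−12): perfect agreement then yields a large finite z instead of
infinity, which would poison the average. Raters whose rating vector (or
whose leave-one-out mean) is constant are dropped with a warning rather
than assigned r = 0 — an undefined correlation is not evidence of zero
agreement. The CI uses the normal quantile on the z scale with the SE of
the individual z's.

**Krippendorff's α** is computed from the coincidence matrix over
stimulus columns, α = 1 − D_o/D_e, with a selectable difference metric.
The default is the interval metric δ²(c,k) = (c−k)², consistent with the
parametric treatment of the 1–9 scale elsewhere in the pipeline; ordinal
and nominal metrics are available. The bootstrap resamples stimulus
columns with replacement (the simplest scheme consistent with reporting
the mean of the replicates); a pair-resampling variant drawing
within-unit value pairs from the coincidence distribution is available
behind `unit="pairs"`.

**ICC(2,1)** (two-way random effects, absolute agreement, single rater)
is computed from the two-way ANOVA mean squares with stimuli as targets.
On balanced data it equals, exactly and not just in expectation, the
variance-component ratio sigma2_item / (sigma2_item + [sigma2_rater +
sigma2_rater_time/n_t] + [sigma2_rater_item + sigma2_res/n_t]) with
untruncated estimates — a property the tests assert on random instances.

**Kendall's W** uses within-rater mid-ranks and the standard ties
correction (the 9-point scale guarantees ties). **Cronbach's α** is
included for comparison only and its result is flagged as a consistency
coefficient: it is inflated by the number of raters and blind to rater
offsets.

## Variance components and beholder indices

On balanced data the five cluster variances plus residual are estimated
in closed form from expected mean squares (Henderson's method 1), with
the stimulus × session and three-way strata pooled into the residual.
Negative solutions are truncated to zero *after* all components are
computed (not sequentially); truncation is standard practice and its
small upward bias is documented — recovery tests therefore run with
truncation disabled so that zero-variance components average to zero
across seeds.

Unbalanced tables fall back to REML. Plain EM for variance components
converges at a linear rate far too slow for a tight tolerance, so the
implementation runs a few monotone EM sweeps and then attempts an
average-information (Newton-type) update each iteration, falling back to
the EM step whenever the AI step fails or lowers the restricted
likelihood. Convergence is declared when the restricted log-likelihood
gain drops below 1e−8 (default cap 500 iterations); non-convergence
raises an error carrying the iteration trace. On balanced data with
interior solutions the REML and closed-form estimates agree to ~1e−10,
which the tests assert at 1e−4. The dense linear algebra is adequate for
the moderate problem sizes where unbalanced tables occur; the balanced
study design always takes the closed-form path.

The beholder indices are bi1 = s2_ri / (s2_i + s2_ri) and
bi2 = (s2_r + s2_ri) / (s2_i + s2_r + s2_ri). Session-related clusters
and the residual are excluded from both denominators: they are neither
stable taste nor signal. bi1 treats rater bias as meaningless scale use;
bi2 counts it as private taste. `include_time=True` adds the session
clusters for sensitivity analysis. Because bi is a ratio of variance
components, no CI is attached. The exact formulas follow the verbal
definition of the index — the ratio of private to total time-stable,
non-residual variance — and satisfy bi2 ≥ bi1 whenever rater variance is
positive.

## Inference and power

Comparisons of agreement between styles operate on each rater's
Fisher-z-transformed leave-one-out correlation, paired within rater
(raw-scale comparison is a caller choice). Directional hypotheses use
one-tailed paired t-tests with Holm step-down adjustment; the df
convention is n − 1 throughout. Equivalence uses TOST with bounds
expressed in dz units (±sesoi_dz · sd of the paired differences); the
SESOI of dz = 0.5 corresponds to 0.1 raw MM1 points at sd 0.2. The TOST
p-value is the larger of the two one-sided p's, and the TOST/NHST
quadrant yields one of four verdicts: equivalent, different,
different-but-within-SESOI, or inconclusive.

The Wilcoxon signed-rank fallback drops zero differences, mid-ranks ties,
uses the exact convolution distribution for n ≤ 25 without ties, and the
normal approximation with continuity and tie corrections otherwise.

Power for the paired t-test is exact via the noncentral t distribution
(ncp = dz·√n, df = n − 1); the sample-size solver does a doubling-plus-
bisection search for the minimal n. TOST power at true effect θ is
F_nct(−t_crit; df, (θ−Δ)√n) − F_nct(t_crit; df, (θ+Δ)√n), floored at
zero. At the planning settings (n = 60, bounds ±0.5 dz, α = 0.05, θ = 0)
this standard formula — and a 20,000-replicate simulation — give ≈ 0.97;
a sometimes-quoted value of 0.99 for these settings is not reproduced by
either route, and the package reports the computed value. Wilcoxon power
is simulation-only (Gaussian differences, seeded, with binomial SE);
at n = 60, shift 0.1, sd 0.2, two-sided α = 0.017 it is ≈ 0.90
(one-sided would give ≈ 0.94). Sidedness defaults: one-sided for the
directional planning computations (which reproduces 95% power at n = 60),
two-sided for the Wilcoxon planning number.

## The synthetic generator

The generator emulates the study design — 62 raters, 22 singers × 3
melodies × 5 styles = 330 stimuli, 2 sessions — and is the package's
test bed: it produces data whose true variance structure is known.

Defaults were chosen once to emulate the published summary statistics of
the voice-preference study the design comes from: per-style means 3.81
(infant-directed speech) to 5.42 (pop) Likert points; sigma2_item = 0.7,
sigma2_rater = 1.6, sigma2_rater_item = 1.1, sigma2_time = 0.02,
sigma2_rater_time = 0.25, sigma2_res = 1.8 (squared Likert points). These
imply bi1 ≈ 0.61, bi2 ≈ 0.79, test–retest r ≈ 0.5 and per-style MM1
≈ 0.51 — all within the ranges the study reports. The stimulus effect is
split into a style-invariant singer-quality component (share rho_q,
default 0.2, giving interstyle agreement ≈ 0.5) and a style-specific
remainder, so interstyle consistency is tunable without touching
rater-side components.

Item, rater-item and residual variances (and the style means) may be set
per style; the rater- and session-side effects are global scalars because
raters and sessions are shared across styles in the crossed design. The
RNG is partitioned into independent per-cluster streams, item-side first,
so enlarging the rater panel leaves item effects — and existing raters'
private-taste draws — unchanged.

Discretization is round-and-clip to 1–9: the simplest mechanism that
yields integer Likert data. It shrinks variances slightly (clipping
compresses the tails; the default configuration loses ~10–15% of the
residual variance), which is why parameter-recovery tests run in
continuous mode. What the generator does *not* emulate: non-Gaussian
taste distributions, ordinal threshold response processes, rater drift
beyond the rater × session term, and any acoustic structure of the
stimuli. Passing recovery tests therefore show the estimators are correct
under the model's assumptions, not that real ratings satisfy them.

## Exclusion rule and pipeline conventions

The registered participant filter drops a rater when one scale value
accounts for strictly more than 85% of their trials, pooled over both
sessions and all styles (the most conservative reading of "trials");
per-session evaluation is available via a flag. The filter is idempotent.

Unbalanced tables are accepted by I/O but rejected with an explicit error
by operations that require the complete crossed design (session
averaging, VCA, grand averages) — no silent listwise deletion. Per-style
MM1 is computed on session-averaged ratings by default, consistent with
the pooling used for the interstyle analysis.

The pipeline's H1A verdict requires all three directional singing
contrasts to be significant after Holm adjustment; partial significance
reports "not supported" with per-contrast detail. Interstyle agreement
reuses the same MM1 implementation with styles as rows; the "highly
consistent" verdict requires the CI lower bound to reach the 0.8
threshold (boundary inclusive). In the degenerate case where all
per-rater z's are identical across two styles, the pipeline reports a
non-significant directional contrast (p = 1) and, for identical vectors,
trivial equivalence, rather than erroring out of the whole report.
Reports are plain dicts, JSON-serializable and bit-reproducible for a
fixed config seed.

## Problem sizes used in the checks

The bundled checks run at the sizes a laptop handles comfortably: design
emulation and recovery at the full study size (62 × 330 × 2; the
closed-form estimator makes 50-seed recovery cheap), sweeps on a reduced
design (20–30 raters, 16–32 stimuli per style), 5,000-replicate type-I
calibration, 10,000-replicate Wilcoxon power, and 20,000-replicate
Monte Carlo cross-checks of the closed-form power formulas.

## Known limitations

- The ANOVA estimator assumes the balanced crossed design; missingness
  routes to dense REML, which scales to moderate sizes only.
- Truncation at zero biases small variance components upward; bi ratios
  inherit that bias near the boundary.
- Discretization is not an ordinal response model; absolute-agreement
  measures on discretized data are mildly attenuated relative to the
  continuous ground truth.
- Bootstrap CIs for Krippendorff's α treat stimuli as the only resampling
  unit by default; rater-level uncertainty is not propagated.
- Cronbach's α is reported only to quantify how much a consistency
  coefficient overstates agreement; it should not be interpreted as
  shared taste.
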