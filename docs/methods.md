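# Methods

This note documents the models, the synthetic-data generator, the fitting
and comparison procedures, and the numerical choices behind `wmbias`, in
enough detail to judge what the package's tests do and do not establish.

## Circular representation

All stimulus, probe and response values are angles on a 360° feature wheel.
Positional angles live in [0, 360); signed offsets in (−180, 180], with the
antipode mapped to +180 so ties break deterministically toward the positive
side. Model densities are probability **masses** on a fixed grid of 360
points (1° per bin), matching the 360-valued stimulus wheels of the
emulated experiments; normalization is the discrete sum over the support,
not a per-radian integral. The von Mises family is closed under pointwise
products, so the normalized grid product of two von Mises masses is exactly
the grid von Mises with resultant-summed parameters — the closed form
(`vm_product_closed_form`) is retained purely as a test oracle; the joint
density itself is always computed by literal pointwise multiplication and
renormalization. Refining the grid tenfold moves product means by well
under 0.01°, so 1° resolution is not a limiting approximation.

The equiluminant color wheel is a circle of radius 60 in the CIE L\*a\*b\*
a\*–b\* plane centred at (a\*, b\*) = (20, 38) with L\* = 70. Index 0 is
placed at phase 0 (the a\* axis) and hue increases counterclockwise; phase
and direction are display conventions with no effect on any analysis, and
no Lab→RGB conversion is attempted. The shape space is treated as a purely
abstract 360° circle — shape identities never enter any computation, only
their angles.

## Observer models

* **Standard WM (baseline).** (1−g)·vM(S_M, κ) + g·uniform — the classic
  delayed-estimation mixture of a memory component and uniform guessing.
  Used to estimate per-participant memory precision κ_M from baseline
  trials, and as the generative response rule on baseline trials.
* **Joint density.** Normalized product of memory and probe densities. Its
  circular-mean displacement toward the probe is
  atan2(κ_P sinΔ, κ_M + κ_P cosΔ). Note the displacement is *not* monotone
  in Δ over the whole sampled range: it increases up to
  Δ\* = arccos(−κ_P/κ_M) (e.g. ≈ 104.5° for κ_P/κ_M = 0.25, ≈ 95.7° for
  0.1) and flattens/declines slightly beyond, though over 16–90° it is
  strictly increasing for any positive precisions. The positive
  distance–bias correlation this produces is what the analyses test.
* **Mixture density.** α·vM(S_M, κ_M) + (1−α)·vM(S_P, κ_P), with α the
  memory-based report proportion. Skews the response distribution toward
  the probe without moving its mode (for α above ~0.7 and separations
  beyond ~40°).

`model_bias` reports the circular-mean displacement with the sign positive
toward the probe, matching the sign convention of the behavioral offsets.

## Synthetic-data generator

The generator reproduces the statistical structure of three designs:

* **exp1** — 12 blocks × (12 baseline + 36 comparison) trials; one probe at
  an integer distance uniform on [16°, 105°], side equiprobable; binary
  similar/dissimilar judgment.
* **exp2** — 40 trials in each of four conditions (short/long-delay
  baselines; same-side and opposite-side probe conditions); two 2AFC probe
  pairs, each a similar probe at 16–45° plus a dissimilar probe 180° from
  it, with the two similar probes on the same or opposite sides of the
  target.
* **exp3** — 4 blocks × (15 baseline + 15 experimental) trials with a
  single 2AFC judgment; an individual-differences design over a population
  whose κ_M is log-normal.

Angles are drawn on integer degrees because the experimental wheels have
360 discrete values. Probe distances are sampled uniformly within their
ranges (the sources specify the ranges but not the sampling law; uniform is
the natural default and is configurable).

Choices the data sources leave open, fixed here once:

* **Similarity-judgment rule.** P(similar) is logistic in the distance
  between the probe and the trial's *noisy memory sample* X_M ~ vM(S_M,
  κ_M): 0.5 at the criterion c (default 60°, near the midpoint of the exp1
  probe range) with slope β (default 15°). Conditioning on X_M rather than
  S_M makes identical physical distances elicit different judgments on
  different trials, producing the ambivalent-distance trials the analysis
  needs.
* **Response generation.** Lapses (default rate 0.05) are uniform reports
  rated confidence 3. Otherwise the joint observer integrates each
  judged-similar probe into the current memory density sequentially (each
  2AFC chosen probe with weight κ_P against the running product — the
  two-step mechanism for exp2 is unspecified in the sources; sequential
  integration reproduces the same-side amplification and opposite-side
  cancellation), and samples the discrete result. The mixture observer
  reports the memory with probability α, otherwise one of the
  judged-similar probes. Trials with no judged-similar probe fall back to
  the baseline density.
* **Confidence.** Non-lapse reports are high confidence (1) with
  probability 0.8, else low (2) — chosen so high-confidence retention
  (~76% after lapses) sits in the >68% range reported for such tasks.
* **Default precisions.** κ_M = 12 and κ_P = 2 for the shared-observer
  cohorts: with these, the mean similar-judgment bias lands in the 5–8°
  range typical of the phenomenon, and the σ≈17° baseline spread is
  realistic for color/shape delayed estimation. The exp3 population draws
  κ_M from LogNormal(ln 12, 0.4), spanning roughly 5–30 — a plausible
  between-subject precision range. Delay conditions are represented only as
  (optionally) distinct κ_M values; timing is metadata.

Per-participant RNG substreams are spawned from the master seed, so tables
are byte-identical across runs and independent of cohort size.

What the generator does **not** emulate: reaction times, display timing,
practice/fatigue, sequential dependencies between trials, non-uniform
guessing, and any shape/color asymmetries. Passing end-to-end tests
therefore shows the pipeline recovers the phenomena *under these generative
assumptions*, not that real data must exhibit them.

## Behavioral pipeline

Signed offsets take the trial's reference probe (the single probe in exp1;
the first pair's similar probe in exp2/exp3) as positive direction;
baseline offsets get i.i.d. random signs, reproducing the convention that
makes baseline means zero in expectation. Analyses default to
high-confidence (rating 1) trials, with per-cell retention reported. Group
statistics are two-tailed one-sample or paired t tests on participant
means, with Cohen's d = mean/SD of the participant-level values and 95%
CIs from the t distribution. The ambivalent-probe analysis bins probe
distances (default 5° bins; the sources report ambivalent distance ranges
but not a granularity) and, per participant, averages similar- and
dissimilar-judged mean offsets over bins containing both judgment types.
Distribution plots use 30°-box-smoothed per-degree proportions, with
Cousineau–Morey within-subject SEMs. Precision is the ML concentration of
a mean-zero von Mises on baseline high-confidence offsets (Bessel-ratio
inversion; estimates are capped at 10⁴ and flagged when the data are
degenerate). The precision–bias correlation is Pearson's r with a 3-SD
bivariate outlier rule, always reported both with and without exclusions.

Power utilities compute minimal n exactly from the noncentral t
distribution (one-sample test) and from the Fisher-z normal approximation
(correlation test), both two-tailed at α = .05 by default; these settings
reproduce the planned cohort sizes of 15, 22 and 99.

## Fitting and model comparison

The fitting objective minimizes |model-expected average signed error −
observed average signed error| over high-confidence comparison trials,
collapsed across probe distances. The model's expected signed error per
trial is the density-weighted arithmetic mean of wrapped signed offsets —
the exact expectation of the quantity whose empirical counterpart is the
observed mean signed error. (For the symmetric joint density this
coincides with the circular-mean displacement; for the mixture the two
differ at large separations, and using the arithmetic expectation is what
makes the estimator consistent.) A sampling-based objective would estimate
the same expectation with Monte-Carlo noise; the analytic form is used
throughout.

κ_P is scanned on a log-spaced grid (0.1–100, 61 points), zoomed twice,
then polished with a bounded scalar minimization — reproducible and
gradient-free for a one-parameter problem. The mixture adds α on a 0–1
grid (step 0.01). Because one scalar objective cannot pin two parameters,
all (α, κ_P) candidates within 0.5° of the minimum objective are kept and
the summed log-likelihood selects among them, after which α is refined
analytically (the objective is linear in α). This tie-break is the
package's own identifiability choice; recovery simulations show it returns
the generating α to within ±0.1 at 300 trials.

Per-trial likelihoods are the discrete density's mass at the observed
response bin, computed exactly on the grid. AIC = 2k − 2LL and
BIC = k ln n − 2LL with k summed over participants' free parameters and n
the total trials entering the fits — BIC's n counts trials, not
participants, because the likelihood is a product over trials. Cohort
comparisons sum per-participant log-likelihoods; fitting a single pooled
participant is the alternative reduction and is available by simply
passing pooled trials. κ_M provenance is an explicit argument of every
fit: by default it is estimated from the same table's baseline condition
via the standard WM mixture (κ component only), but a cross-experiment or
known value can be supplied.

Recovery studies use a vectorized trial generator
(`simulate_fit_trials`) that draws integer probe distances and responses
directly from the generating density — the controlled setting in which an
estimator's recovery can be assessed. Problem sizes for the bundled
studies (50 replicates × 300 trials for parameter recovery; 20 replicates
× 16 participants × 300 trials per generator for model recovery) were
chosen to make medians and preference rates stable across seeds.

## Known limitations

* The judgment and confidence rules are plausible but invented; inference
  about them from real data is out of scope.
* Fits assume the judged-similar subset is generated entirely by one model;
  hybrid observers (e.g. integration plus occasional swaps) are not
  implemented.
* The mixture fit's κ_P is weakly identified by design (the tie-break
  resolves a true ridge); only α should be interpreted quantitatively.
* Hierarchical/Bayesian fitting across participants is not provided.
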