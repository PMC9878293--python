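# Methods

## Noise model

A noise field on an `N × N` grid (`N` even, ≥ 32; default 512) is

```
noise(x) = Σ_s Σ_θ Σ_φ Σ_p  w[s, θ, φ, p] · 1_p(x) · sin(2π c_s (x·u_θ)/N + φ)
```

with scales `c_s ∈ {2, 4, 8, 16, 32}` cycles per image, orientations
`θ ∈ {0°, 30°, …, 150°}`, phases `φ ∈ {0, π/2}`, and each scale tiled into
`(c_s/2)²` square patches `p` (two grating cycles per patch). Every patch of
every (scale, orientation, phase) layer gets an independent weight
`w ~ U(−1, 1)` — 4,092 weights at the defaults. This is the standard
sinusoid parameterization for face classification images, chosen so CIs are
visually comparable to the wider RC literature. The uniform weight interval
must be symmetric about 0, making the noise ensemble zero-mean pixel-wise.

Each stimulus pair is a field and its exact negation on one base face. The
expansion from weights to pixels is linear and sign-symmetric in IEEE
arithmetic, so `expand(−w) = −expand(w)` holds exactly — the pair-cancellation
invariant is exact, not approximate.

**Randomness.** Field `i` of a set is drawn from
`SeedSequence(seed, spawn_key=(i,))`: counter-based, so generation is
order-independent and parallel-safe, and a `(seed, params, n_pairs)` triple
regenerates every weight and PNG bit-identically.

**Rendering.** `pixel = clip(base + display_scale · noise, 0, 1)` quantized
to 8 bits. `display_scale` is one constant per stimulus set, chosen so the
set's largest |noise| maps to a configurable fraction (default 0.4) of the
dynamic range; a single shared constant keeps rendered pairs exact inverses
about the base face, at the cost of slightly lower contrast than per-image
autoscaling would give. CIs are rendered with the same constant so self- and
anti-CIs are comparable.

**Base faces.** Any square grayscale image, resampled bicubically to the
grid size (logged). The bundled `synthetic_base_face` is a deterministic
Gaussian-blob face-like pattern — a synthetic stand-in with the gross
figure/ground luminance structure of a composite face photograph but no
photographic content; studies with real composites should load their own
image.

## Classification images

The self-CI averages the noise of the chosen stimuli over *answered* trials;
the anti-CI averages the unchosen members; group CIs pool answered trials
across sessions (trial-weighted). Non-responses (the 3-s deadline) are
excluded from every average and counted, never imputed. Averaging is done in
weight space and expanded once — algebraically identical to averaging pixel
matrices, cheaper, and it preserves the exact self/anti cancellation.
Answered trials are sorted by pair id before averaging so the floating-point
mean is invariant to presentation order.

Filler-CIs (controls for the resemblance manipulation check) are built as
group CIs of simulated uniform-random choosers, flagged `kind="filler"`. The
resemblance check averages the filler ratings within participant by default
(a per-filler long-format variant is available) and runs a two-tailed paired
t-test, refusing zero-variance difference vectors.

## Computational scoring

`score(stimulus) = (raters choosing it) / (raters answering its pair)`. The
denominator counts only raters who answered that pair, which preserves the
within-pair complement under rater non-response. The second member's float
is stored as `1 − score(first)`; since `a + fl(1 − a) = 1` for all
`a ∈ [0, 1]` in IEEE double arithmetic, the complement invariant holds
exactly at the float level. Pairs with zero answers are a hard coverage
error; pairs with fewer than 10 raters trigger a warning (the threshold is
configurable, because realistic rater counts per pair vary by design).

The computational score of a session is the mean of the chosen stimuli's
scores over answered trials, accumulated as exact rationals
(`fractions.Fraction` of the integer counts) with the float derived at the
end. Consequently `score(self-selections) + score(anti-selections) = 1`
exactly on fully answered sessions; the float printed for a single stimulus
may differ from its rational by ≤ 1 ulp. Scoring refuses sessions from a
different stimulus set — positivity scores are meaningless for unseen noise
— and, by default, sessions whose task is not resemblance.

Table CSVs print scores at 12 significant digits; on reload the exact counts
are recovered as `round(score · n_raters)`, which is lossless because the
stored float is the correctly rounded count ratio.

A split-half diagnostic (correlation of table scores across random rater
halves, averaged over splits) is provided to gauge table stability.

## Reliability and association statistics

- **Cronbach's α** = `k/(k−1) · (1 − Σ item variances / total-score
  variance)`, n−1 variances. Reverse-keyed columns are declared on the
  rating matrix and recoded as `scale_min + scale_max − x` before anything
  is computed (a bipolar adjustment scale typically reverse-keys its
  negative item, e.g. emotional instability).
- **ICC** from the two-way decomposition (targets × raters, complete data
  required): `ICC(2,k) = (MSR − MSE)/(MSR + (MSC − MSE)/n)`,
  `ICC(3,k) = (MSR − MSE)/MSR`; p from the F test of `MSR/MSE` with
  `(n−1, (n−1)(k−1))` df — one of several defensible p-value conventions,
  stated rather than asserted as canonical. Note `ICC(3,k) ≥ ICC(2,k)` is
  guaranteed only when `MSC ≥ MSE`; with fewer raters than error the
  ordering can invert by sampling noise.
- **Pearson r** (scipy) with two-tailed p from the t transform, n−2 df;
  Fisher-z 95% CIs where reported.
- **Paired t** (scipy) with n−1 df and a 95% CI on the mean difference.
- **Standardized OLS** (statsmodels): y and predictors are z-scored with
  the n−1 SD, the model is fitted with an intercept (exactly 0 on
  standardized data, not reported), and slopes are the standardized β with
  t(n − p − 1), two-tailed p and 95% CIs. With one predictor β equals the
  Pearson r. Rank-deficient designs raise a collinearity error naming the
  offending predictors.

For complete data, averaging the 7 valence items within rater and then
raters per target equals the opposite order; the rating matrix therefore
requires completeness instead of choosing an order.

All p-values are two-tailed; no multiple-testing correction is applied
(stated in CLI output).

## Synthetic studies and parameter recovery

The simulator is the toolkit's evidence that each stage measures what it
claims, in the absence of bundled human data.

- **Latent stimulus positivity**: per pair, `q_first ~ U(0, 1)`,
  `q_second = 1 − q_first`. This is the quantity the positivity table
  estimates.
- **Participant model**: `P(choose first) = logistic(d·(v − 0.5)·(q₁ − q₂))`
  with self-valence `v ~ U(0, 1)` and decisiveness
  `d ~ LogNormal(µ=2.0, σ=0.5)` (median ≈ 7.4). The logistic
  valence-matching rule is the minimal mechanism by which people with a more
  positive self-image preferentially select positive-looking stimuli; the
  decisiveness spread makes the v→score mapping heterogeneous across
  participants, as real choice consistency is. Trials time out with
  probability 0.02 — non-responses occur but are rare under a 3-s deadline.
- **Positivity raters**: `P(choose first) = logistic(3·(q₁ − q₂))`. The
  slope 3 makes raters clearly informative while keeping the expected table
  score a near-linear function of q; much steeper raters would push the
  table toward a step function of sign(q − ½), which caps its linear
  correlation with q.
- **Item ratings**: `clip(round(1 + 8·valence + item_bias + N(0, σ)), 1, 9)`
  per item, biases `N(0, 0.5)` drawn once, σ = 1 by default — 9-point
  bipolar items whose mean tracks the latent valence with realistic rater
  noise. Each self-CI's latent valence is the mean true q of its selections.

The reference study uses 200 participants, 40 positivity raters, 300 pairs,
30 item raters × 7 items. Under those conditions the recovery report shows
r(CS, v) ≈ 0.94, r(CS, simulated ratings) ≈ 1.0, and r(table, q) ≈ 0.97;
the toolkit's acceptance tests require r(CS, v) > 0.7 and r(table, q) > 0.9,
thresholds set by pilot simulation of the generative model. Simulated
stimuli default to 128 px because resolution affects only PNG rendering,
never a scored quantity.

**What passing recovery does and does not show.** It shows the pipeline's
bookkeeping and estimators are correct under a plausible generative model.
It does not show that real participants follow a logistic valence-matching
rule, that real q differences are uniform, or that real rating noise is
Gaussian; empirical validity claims still require human data. The
simulator also omits trial-order effects, fatigue, and any dependence of
non-response on difficulty (timeouts are independent of |q₁ − q₂|).

## Numerical and degenerate-input policy

- Exactness claims (pair complement, self/anti cancellation, complement
  conservation) are engineered, not assumed: negation in weight space,
  `1 − a` complements, rational accumulation.
- Zero answered trials, zero-variance differences, constant vectors and
  rank-deficient designs raise typed errors rather than returning NaNs.
- Sessions are validated against the manifest (duplicate/unknown pairs are
  hard errors; over-deadline response times are warnings).
- All simulation outputs are byte-reproducible from the config seed; stage
  RNGs are derived with disjoint `SeedSequence` spawn keys.

## Limitations

- Composite base-face construction (morphing, alignment) is out of scope;
  the synthetic face is a stand-in, not a substitute for real composites.
- No cluster-based pixel significance testing of CIs; CIs here are
  descriptive averages.
- Scoring dimensions other than positivity (competence, dominance) would
  follow the same recipe but ship unvalidated.
- The choice model is not fitted to real trial logs (no inverse inference).
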