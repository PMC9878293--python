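# revcorr

A toolkit for **reverse-correlation (RC) studies of self-image**: it generates
sinusoid-noise face stimuli, builds **classification images of self (self-CIs)**
from two-alternative forced-choice trial logs, and scores the valence of a
self-CI two ways — by aggregating independent ratings, or with a rater-free
**computational scoring method** based on per-stimulus positivity scores.
A synthetic-participant simulator with known latent parameters makes the whole
pipeline testable by parameter recovery, without any human data.

Intended users: researchers in social/visual cognition and computational
psychometrics who run RC tasks and want a reproducible, scriptable pipeline
from stimulus generation to reliability statistics.

## The method

**Stimuli.** A noise field is a weighted sum of truncated sinusoid gratings —
5 spatial scales (2, 4, 8, 16, 32 cycles/image) × 6 orientations × 2 phases,
each scale tiled into independent patches, giving 4,092 i.i.d. uniform weights
per field. Every trial shows an *inverse pair*: a noise field and its exact
negation superimposed on one grayscale base face. A participant completes 300
trials choosing the image that looks more like themselves (3-s deadline;
timeouts are recorded as non-responses). The **self-CI** is the average of the
selected noise fields rendered over the base face; the **anti-CI** averages
the non-selected members. Because the pairs are exact inverses, on a fully
answered session the self-CI and anti-CI noise cancel exactly.

**Computational scoring.** A one-off positivity-judgment RC run ("Which one
looks more positive?") over the same stimuli gives every stimulus a
**positivity score**: the fraction of raters who chose it within its pair —
if 40% chose the left member, the left scores 0.4 and the right 0.6, summing
to 1 exactly. The **computational score (CS)** of any resemblance session is
then the mean positivity score of its selected stimuli (selections scoring
0.4, 0.5 and 0.6 average to 0.5); non-response trials are averaged out, never
imputed. CS is a rater-free stand-in for the mean of seven 9-point bipolar
valence items aggregated over independent raters.

**Statistics.** Cronbach's α, ICC(2,k)/ICC(3,k) from the two-way ANOVA
decomposition, Pearson r with two-tailed p, paired t-tests, and multiple
regression reported as standardized β with t(n − p − 1) and 95% CIs.

**Simulation.** Each synthetic stimulus pair carries a latent positivity
q ∈ [0, 1] (complementary within the pair); each synthetic participant has a
latent self-valence v ∈ [0, 1] and decisiveness d, choosing the first member
with probability logistic(d·(v − 0.5)·(q₁ − q₂)); positivity raters use
logistic(slope·(q₁ − q₂)). Recovery of v by CS and of q by the positivity
table validates the pipeline end to end.

## Worked example

Run a full synthetic study with the default conditions (200 participants,
40 positivity raters, 300 pairs):

```bash
$ revcorr simulate --out run --seed 1
recovery: r(score, valence) = 0.937, r(score, ratings) = 0.998, r(table, q_true) = 0.975; outputs in run
```

- `r(score, valence) = 0.937` — computational scores recover the latent
  self-valence the choices were generated from.
- `r(score, ratings) = 0.998` — CS agrees with simulated independent
  valence ratings of the same self-CIs, the relationship the scoring method
  is designed to replace.
- `r(table, q_true) = 0.975` — the positivity table recovers the true
  stimulus positivity.

`run/` then contains the trial logs, the positivity table, per-participant
scores, the latent ground truth, a JSON recovery report, and PNG renderings
of the group positive-CI, anti-positive-CI and group self-CI. The first
scored participants:

```
participant_id session_id    score  n_trials_scored  n_trials_skipped
        pp0000 res_pp0000 0.387155              290                10
        pp0001 res_pp0001 0.447727              297                 3
```

Other commands: `revcorr gen-stimuli` (stimulus PNGs + manifest),
`revcorr build-ci`, `revcorr build-table`, `revcorr score`,
`revcorr reliability`, `revcorr correlate`. Every command is a thin wrapper
over the `revcorr` Python API (`build_stimulus_set`, `build_ci`,
`build_positivity_table`, `computational_score`, `recovery_study`, ...).

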