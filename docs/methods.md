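# Methods

`policypulse` measures how public attitude expressed in short social-media
comments responds to policy announcements. It chains three instruments: a
rule-based sentiment scorer, a daily aggregation into a normalized attitude
series, and interrupted time-series (segmented) regression at known policy
dates. A synthetic-data module generates every input with known ground
truth so the whole chain is testable offline.

## Comment scoring

A comment arrives pre-tokenized with an optional terminal punctuation run.
Its raw score is

    E = P * Σ_j (−1)^{N_j} · W_j · Π_{q in scope(j)} L_q

where `W_j` is the signed lexicon weight of the j-th sentiment word, `N_j`
the number of negator words in its scope, `L_q` the intensity multipliers
of degree adverbs in its scope (large 2.0, medium 1.5, small 0.5), and `P`
the terminal punctuation intensity (`!`→1.5·n for runs of n≥1, `?`→1.2·(n−1)
for n≥2, `~`→0.8·n). Comments are labeled positive (E > 0), neutral
(E = 0) or negative (E < 0). Assumptions: modifiers act multiplicatively
and locally; unknown tokens are neutral; punctuation scales the whole
comment, not individual words.

Design choices made where the rule is genuinely open:

- **Scope boundary.** "Before the j-th sentiment word" is bounded at the
  previous sentiment word (or the comment start), so each negator/adverb
  attaches to exactly one sentiment word. Without a boundary, modifiers
  would multiply into every later word and the sum would not decompose.
- **No matching punctuation rule** (empty, mixed symbols like `!?`, or a
  run below the rule's minimum length) is neutral: P = 1.
- **Semantic shift.** When an embedding table is supplied, the comment is
  split at its token midpoint and the mean embeddings of the sentiment
  words in the two halves are compared; cosine similarity < 0 (angle
  > 90°) flags a likely rhetorical shift (sarcasm, concession). Whether a
  flag inverts the second half's contribution is opt-in
  (`invert_on_shift`, default off): detection is well-defined, the score
  adjustment is a modeling judgment. Equality at exactly 90° does not
  flag.
- **Tokenization is an input contract.** Comments arrive pre-tokenized (a
  whitespace splitter is provided); Chinese word segmentation or any other
  segmenter is pluggable upstream. This keeps the scorer
  language-agnostic and exactly testable.

## Daily attitude series

Neutral comments are treated as objective statements and excluded. Per
calendar day the raw scores of non-neutral comments are averaged; days with
no non-neutral comment receive the pre-normalization series mean and are
flagged `imputed` (gaps are a property of the sample, not evidence of
neutrality). The series is then min–max normalized over the full study
window into [0, 1]; a constant series maps to 0.5. The affine parameters
(`norm_offset`, `norm_scale`) are stored so raw-scale quantities can be
mapped onto the normalized scale — recovery experiments need this, and any
downstream effect size is otherwise scale-ambiguous. Min–max over the
window was chosen over z-scoring because the [0, 1] bound is part of the
series' definition; its cost is that the scale depends on the window's
realized extremes, which attenuates nominal effect sizes in small samples
(see the end-to-end experiment below).

## Segmented regression (ITSA)

For a series `y_t` and an intervention at day `t0`:

    y_t = β0 + β1·time_t + β2·level_t + β3·trend_t + Σ_k [a_k sin(2πkt/T) + b_k cos(2πkt/T)] + ε_t

with `time_t` days since the series start, `level_t = 1[t ≥ t0]` (the
intervention date itself counts as post), `trend_t` days since `t0` (0
before). `β2` is the immediate attitude change, `β3` the change in slope.
Estimation is OLS; the model assumes a correctly-dated, sharp interruption
and piecewise-linear trends.

- **Autocorrelation.** First-order residual autocorrelation is diagnosed
  with Durbin–Watson (`Σ(e_t−e_{t−1})²/Σe_t²`, in [0, 4], ≈2 when white).
  When DW < 1.5 or DW > 2.5 (config-exposed), OLS standard errors are
  replaced by Newey–West HAC standard errors with Bartlett weights
  `1 − ℓ/(L+1)` and default lag `L = floor(4·(n/100)^{2/9})`, the standard
  rule of thumb. Coefficients are unchanged; only inference is corrected.
  Note DW near 4 signals strong *negative* autocorrelation and therefore
  also triggers the correction.
- **Inference.** Two-sided p-values use the t distribution with n − p
  degrees of freedom, also under HAC (common ITSA practice; HAC t-statistics
  are asymptotically normal, and the t reference is the conservative
  finite-sample convention).
- **Seasonality.** Fourier pairs with period T (default 365.25 days,
  K = 2 when enabled) absorb seasonal cycles without committing to month
  dummies. Per-event panel fits default to K = 0 because their windows
  (≤ 90 days per side) are shorter than a seasonal cycle.
- **Counterfactual.** The pre-trend projection `β0 + β1·time (+ seasonal
  terms)` with level and trend zeroed; it equals the fitted values exactly
  before the intervention, and the observed-minus-counterfactual gap after
  it is the realized effect.
- **Policy panel.** Each policy date is fitted in isolation
  (single-interruption model per event) on a window spanning to the
  neighboring events, capped at 90 days per side; events with fewer than 7
  observations on a side are skipped with a warning. Isolated per-node
  fits match how multi-policy timelines are usually reported; the cost is
  that overlapping windows are not independent across rows.

## Coding statistics

- **Intercoder reliability** is percent agreement: the fraction of
  comments whose full label sets are identical between two raters
  (strictest reading of "same coding result"); a Jaccard-overlap variant
  is available for sensitivity analysis. Consensus after adjudication is
  an input, not computed.
- **Category tables** report, per calendar month, 100 × (comments carrying
  a category) / (comments in the month); multi-label comments count in
  every category they carry, so columns need not sum to 100. Months with
  no comments are missing, not 0. Whether the denominator is all comments
  or only coded ones is a flag (`denominator`), defaulting to all.
- **TF-IDF keywords** use tf = count/document length and idf = ln(D/df)
  with no smoothing, scored as the maximum over documents, ties broken
  lexicographically. The variant is pinned (and config-free) so rankings
  are reproducible; a stop-list is applied before counting.

## Synthetic data: what it emulates and what it does not

The generators stand in for a crawled comment corpus and its derived
series:

- `gen_lexicon` — unit-magnitude sentiment words, negators, and adverbs
  drawn from the three intensity classes.
- `gen_comments` — each comment is assembled so its scored sign matches
  its assigned label with probability 1 − `label_noise`: every sentiment
  term carries the intended sign directly, via a *pair* of negators (sign
  preserved), or via a *single* negator on an opposite-sign word (sign
  flipped). Adverbs and punctuation only rescale magnitudes. The daily
  probability of a positive label follows a base level, an optional linear
  ramp, and step shifts at policy dates (`polarity_drift`); drift operates
  on label probabilities, never on word weights, so the scoring rule stays
  an untouched measurement instrument. Default rates: negation 0.3,
  adverb 0.3, punctuation 0.2, label noise 0.2 — i.e. modifiers are
  common but not dominant, and a fifth of comments contradict their label,
  matching the accuracy band (70–85%) considered reasonable for
  social-media sentiment classification.
- `gen_its_series` — the segmented-regression model run generatively with
  AR(1) noise (`ε_t = φ·ε_{t−1} + N(0, σ²)`, stationary initialization)
  and optional Fourier seasonality; values are clipped to [0, 1] only at
  emission with the clip count reported, preserving linear-model recovery
  when clipping is rare.
- `gen_codings` — a reference coding plus rater copies that match it
  independently with a given probability; a disagreeing copy toggles one
  category so it never silently equals the reference.

Not emulated: real lexical ambiguity (a word's polarity never depends on
context), sarcasm beyond the geometric shift rule, topic structure in the
text, retweet cascades, or bursty comment arrival. Passing tests therefore
demonstrate that the *pipeline* is correct and well-calibrated under its own
assumptions — not that the lexicon rule itself reaches any particular
accuracy on real Weibo text.

## Experiment sizes and numerical choices

Monte-Carlo experiment sizes were chosen so each check has clear power
while remaining desk-scale:

- Scoring-rule oracle: 1,000 random comments (≤ 12 tokens), exact match
  against explicit scope enumeration.
- Classification: 5,000 comments at label noise 0.2; expected accuracy
  0.80 with binomial SE ≈ 0.006, checked against the 0.70/0.60 floor.
- Parameter recovery: 500 series of 180 days, σ = 0.05; means within 2
  Monte-Carlo SEs of truth, 95% CI coverage ≥ 90%.
- HAC behavior: 200 replicates of AR(1) noise with φ = 0.8.
- End-to-end shift recovery: 200 replicates of 90+90 days at 150
  comments/day, one unit-weight sentiment word per comment, adverb and
  punctuation rates 0 so the injected raw daily-mean shift is exactly
  2·δp; δp = 0.03 on top of a +0.17 ramp makes the nominal normalized
  shift 0.06/0.40 = 0.15. An a-priori power computation (design-matrix
  algebra: SE(β2) ≈ σ_day·0.298 with σ_day = 1/√150) gives ≈ 99% sign
  power, against the ≥ 95% requirement. Because min–max normalization
  divides by the *realized* range — inflated by order statistics of the
  daily noise — the per-replicate truth is computed as
  raw shift / (max − min) via the recorded affine parameters, rather than
  assuming the nominal 0.15; the bias of the estimator against that truth
  is what the mean check bounds.

Numerical conventions: rank deficiency is reported with the offending
column names before fitting; Durbin–Watson on an all-zero residual vector
is an error (the statistic is 0/0); noiseless fits recover coefficients to
machine precision and their DW value is numerical noise, which is why the
HAC trigger is irrelevant there; percent cells are rounded to 2 decimals
only at the table boundary.

## Known limitations

- Percent agreement ignores chance agreement; kappa-style statistics are
  out of scope because the reference procedure is defined in terms of raw
  agreement.
- Per-node fits with overlapping windows share data; the panel report does
  not adjust for that dependence.
- The DW→HAC switch is a discrete decision rule; near the thresholds,
  inference can change discontinuously between reruns of similar data.
  `force_hac` sidesteps the rule when robust errors are wanted throughout.
- Min–max normalization couples every value to the window extremes: adding
  data re-scales history. Comparisons across windows should use the stored
  affine parameters.
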