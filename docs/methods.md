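# Methods

## Problem setting

Verbal autopsy (VA) assigns a probable cause of death (COD) from a
structured post-mortem interview, in settings where most deaths occur
outside health facilities. The data object is a binary matrix: one row
per death, one column per yes/no survey symptom (1 = reported present),
plus one cause label per death drawn from a short list of broad cause
groups. The package implements two classifiers over this object, the
assessment metrics that are standard in the VA literature, the
evaluation protocol (stratified cross-validation, a Dirichlet
robustness experiment, Wilcoxon comparison), ICD-10 cause grouping,
and a synthetic generator that stands in for restricted survey data.

## Classification model

**Multinomial naive Bayes over present symptoms.** For cause c and
record x ∈ {0,1}^S,

    score(c | x) = P(c) · ∏_{s : x_s = 1} P(s | c),

i.e. the product runs over symptoms *reported present* only; an absent
symptom contributes no factor. This is the multinomial event model on
the bag of present symptoms, not the Bernoulli model (which would also
multiply 1 − P(s|c) terms for absent symptoms). Training estimates

    P(c)    = n_c / N
    P(s|c)  = (count of s present in class c + α) / (total present count in class c + α·S)

with additive smoothing α (default 1, Laplace; configurable down to 0,
where unseen symptoms zero a posterior — permitted but warned about).
Scores are accumulated in log space and normalised once with
log-sum-exp; VA surveys run to a couple of hundred symptoms and raw
products underflow. Posterior columns and ranking tie-breaks follow a
fixed declared cause order, so repeated runs are bit-reproducible.
`sklearn.naive_bayes.MultinomialNB` implements the same likelihood on
binary input and serves as an independent cross-check in the tests; the
shipped estimator is self-contained.

**One-against-all ensemble (`OneVsRestVANB`).** A dataset with M causes
is decomposed into M binary datasets — cause C_i positive, everything
else negative — and one binary NB is fitted to each. A record's score
for cause C_i is member i's positive-class posterior. Causes are ranked
by descending score, ties broken by cause order. Scores are
deliberately *not* renormalised across members: each is a valid
two-class posterior, and the ensemble compares them directly. The
negative class mixes heterogeneous causes; no reweighting is applied.
The full descending ranking (not just the argmax) is retained, because
all assessment is cumulative by rank.

## Assessment metrics

A record is *correct at depth k* when its true cause appears among its
top k ranked causes. With S_k the fraction of correct-at-k records and
n causes:

- **Cumulative sensitivity** at rank k is S_k (so 60% at rank 1 plus
  15% fresh hits at rank 2 gives 75% at rank 2).
- **PCCC(k)** = (S_k − k/n) / (1 − k/n): zero at chance, one when
  perfect, negative below chance. It is undefined at k = n (`pccc`
  raises; rank tables report NaN there). PCCC is *not* monotone in k:
  writing PCCC(k) = (S−x)/(1−x) with x = k/n, the value falls whenever
  the incremental hit rate is below the chance increment, exactly when
  S_{k+1} − S_k < (1 − S_k)/(n − k). The unit suite asserts this
  characterisation; empirically PCCC does decrease at deep ranks on a
  sizeable fraction of synthetic datasets once hits saturate.
- **CSMF accuracy** = 1 − Σ_j |true_j − pred_j| / (2·(1 − min_j true_j))
  compares cause-specific mortality fractions at the population level;
  bounded in [0,1] because the denominator is the worst achievable
  total error. Causes with zero records in a test split contribute 0
  to the true CSMF (and hence drive the min), and are excluded from
  per-cause sensitivity.

**Rank-k CSMF accuracy (interpretation).** Only the k = 1 predicted
CSMF has a standard definition. For k > 1 this package forms the
*effective assignment* — each record credited with its true cause if
that cause is in its top k, otherwise with its rank-1 cause — and
reports the running maximum over depths 1..k of that assignment's
accuracy. The running maximum is needed because the raw effective
assignment is not monotone: crediting a true cause that is already
over-predicted can increase total CSMF error. The reported value is
therefore "the best population-level agreement achievable using up to
k ranks"; it equals the standard definition at k = 1 and never
decreases with k.

## Evaluation protocol

**Stratified k-fold CV** (default k = 10). Within each cause, records
are shuffled with a seeded generator and dealt round-robin across
folds, remainders to the lowest-index folds; per-cause fold sizes
therefore differ by at most one, and causes with fewer than k records
simply miss some folds. Each fold trains on the other k−1 parts,
ranks causes on the held-out part, and scores all metrics at each
rank; across-fold means are reported alongside per-fold values. A
training part that loses a cause entirely is an error (the one-vs-rest
member could not be built), with the remedy stated in the message.

**Dirichlet test resampling.** To model deployment conditions where
the cause mix differs from training, a CSMF is drawn from
Dirichlet(concentration) over the test set's causes (default symmetric
weight 1 per cause — uninformative, since no particular
parameterisation is canonical), per-cause counts from
Multinomial(N, CSMF), and records are resampled with replacement
within cause. Output size equals input size and contains only copies
of input records, so per-record predictions are unchanged — only the
mix shifts. Population-level accuracy drops markedly under this
perturbation (the acceptance script quantifies the dip), while
separable data keeps perfect rank-1 sensitivity.

**Wilcoxon signed-rank comparison.** Paired metric series (typically
one observation per dataset × rank cell) are compared with a two-tailed
signed-rank test. Zero differences are dropped; ties get mid-ranks.
`exact` mode enumerates all 2^m sign patterns (m ≤ 20); for m
all-positive distinct differences this gives p = 2/2^m. `normal_approx`
uses Z = (W⁺ − m(m+1)/4) / √(m(m+1)(2m+1)/24) *without* continuity
correction; for 35 uniformly signed observations this yields
Z = 5.1594 and two-tailed p = 2.477×10⁻⁷. The approximation's relative
error is small for moderate p but grows without bound in the far tail
(a central-limit statement); the tests assert the 10% sanity band only
where the exact p is ≥ 0.05.

## Synthetic data generator

Symptoms are conditionally independent Bernoulli given cause — exactly
the NB assumption — so generator parameters are recoverable from data
and known-answer tests are possible. An optional pairwise-copying knob
ρ (each odd column overwritten by its left neighbour with probability
ρ) breaks conditional independence to probe the violated-assumption
regime.

- **Separable presets** give cause c a private signature symptom with
  prevalence `signature_strength` under c and `baseline` otherwise.
  At strength 1 and baseline 0 every record shows exactly its cause's
  signature, and any consistent classifier is perfect — the
  known-answer regime used to validate the CV pipeline end to end.
- **Imbalanced presets** mirror the seven study datasets' published
  structure: their cause lists, per-cause death-count proportions
  (e.g. the child preset is dominated by acute respiratory and
  diarrhoeal deaths at ~28% and ~22%, with the rarest cause at 0.04%)
  and symptom counts (88–224). Symptom profiles are random with
  substantial overlap — baseline prevalence U(0.05, 0.25) shared
  across causes, each cause elevating a characteristic 5% of symptoms
  (drawn from a common 30% pool, so causes share markers) by
  +U(0.15, 0.35). These values were calibrated once so that generated
  data reproduces the difficulty regime reported for real VA surveys
  (top-rank cumulative sensitivity roughly 45–60%, rank-5 near 90%)
  rather than being trivially separable.

What the generator does *not* emulate: free-text narratives, age/sex
covariates, physician-coding noise, instrument-specific skip patterns,
and realistic symptom correlation structure (beyond the ρ knob).
Passing tests on generated data therefore validate the algorithmic
pipeline and its known-answer behaviour, not field performance on any
real survey.

## Numerical and design choices

- Smoothing default α = 1; the scale-invariance of fitted parameters
  under record duplication holds exactly for α = 0 only, since a fixed
  pseudo-count intentionally does not grow with the data.
- Ranking ties broken by declared cause order via a stable sort;
  argmax ties resolve to the earliest cause.
- ICD-10 grouping compares 3-character roots (letter block, 2-digit
  number), so a bare bound like B20 covers B20.x/B201. A few codes sit
  in two groups in the published table (D64, G40, R04, R06, Q00–Q99,
  C76, W79, O60 — one of each pair being the Neonatal group);
  resolution is by explicit policy: lowest group number (default),
  always-neonatal, or age-aware (neonatal when age ≤ 28 days), each
  with a logged warning, because the published grouping is plausibly
  age-conditional but no rule is stated.
- Missing survey responses are coded 0 (absent): the binary recoding
  admits only present/absent.
- Problem sizes in the acceptance script (separable CV at N = 3000,
  study-structured CV at N = 3000, Dirichlet experiment at N = 1500
  with 50 resamples, recovery at N = 20000) are chosen so every
  quantity is stable at its reported precision while the whole script
  runs in seconds.

## Known limitations

- Cumulative PCCC can legitimately decrease with rank depth; any
  expectation of monotonicity holds only while incremental hits beat
  the growing chance term.
- One-vs-rest member scores are uncalibrated across members; ranking
  quality, not probability calibration, is the design target.
- The rank-k CSMF accuracy beyond k = 1 is an interpretation (above),
  not a field standard.
- The generator's conditional-independence default matches the
  classifier's assumption; robustness conclusions should use ρ > 0.
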