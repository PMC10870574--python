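# Methods

## The estimand and the model

The quantity of interest is the population-average association between a
session-level exposure — the share of a session's micro-dialogues that
review the previous session's action recommendations ("review percentage") —
and a client-level outcome, the relative change in PHQ-9 or GAD-7 score over
a 50–70 day window, `change = (initial − final)/initial × 100`.

Both variables are transformed before modeling. The change score mixes
negative, zero and positive values with heavy tails, so it enters as the
signed cube root `sign(x)·|x|^{1/3}`. The review percentage is non-negative
with a point mass at zero, so it enters as `log(1 + x)`, which maps zero to
zero and needs no offset choice.

The regression is a Gaussian-family, identity-link GEE with clients as
clusters, an exchangeable working correlation and robust (sandwich)
standard errors. Covariates: micro-dialogues per session, the previous
session's recommendation count, the client's initial score, the assessment
window in days, and therapist and organization fixed effects (dummy coded,
first-observed level as reference, entered uncentered). The interaction
model adds `log(1+review%) × initial score` (and, for depression, `×
dialogues/session`), constructed on the transformed review variable.
Severity-stratified post-hoc fits repeat the main model within each baseline
category without interactions. No multiple-testing correction is applied to
the post-hoc fits; outputs annotate them as exploratory.

Numerical/inference choices worth knowing:

* **Aliasing.** Therapists are nested in organizations, so organization
  dummies are linear combinations of therapist dummies. The design matrix is
  audited by (non-pivoted) QR in priority order — core covariates first,
  therapist dummies, organization dummies last — and dependent fixed-effect
  columns are dropped with a warning. A dependent *core* covariate (e.g. a
  constant within a tiny stratum) is an error; the stratified driver treats
  it as a skipped stratum.
* **Exchangeable dependence cap.** When the outcome is (nearly) constant
  within cluster, the moment estimate of the within-cluster correlation
  approaches 1 and the working correlation becomes singular. The package
  caps the dependence parameter at 0.99. For cluster-constant designs the
  point estimate is invariant to the working correlation, so the cap affects
  only numerical stability.
* **Small-cluster inference.** Stratified fits can have ~50 clusters against
  dozens of fixed-effect columns; the plain sandwich over-rejects there.
  Stratified fits therefore default to the Mancl–DeRouen bias-reduced
  covariance; pooled fits (hundreds of clusters) keep the standard sandwich.
* **Bootstrap.** The nonparametric check resamples *clients* (the cluster
  unit) with replacement, B = 1,000 by default, refits the full model, and
  reports percentile 95% intervals; non-convergent replicates are dropped
  and counted, with >10% failures an error. A Wald-significant coefficient
  is "verified" when the bootstrap interval agrees on excluding zero.

## The synthetic corpus

The generator emulates the structure of a community behavioral-health
dataset with all latent labels observable. Defaults (all configurable):

| Parameter | Default | Note |
|---|---|---|
| organizations / therapists / clients | 14 / 126 / 450 | proportional hierarchy |
| sessions per client | N(5.2, 2.1), min 3 | rounded, capped by window capacity |
| micro-dialogues per session | N(31.5, 7.7), clipped [15, 55] | rounded |
| recommendations per session | N(4.7, 3.2), clipped [1, 8] | rounded |
| review probability per prior recommendation | 0.14 | ⇒ ≈half of sessions contain a review |
| assessment window | uniform 50–70 days | sessions ≥5 days apart |
| outcome effects (PHQ-9) | intercept −1.93; log-review 0.61; interaction −0.02; initial 0.09; dialogues 0.04; prior recs 0.01; days 0.02 | cube-root-change scale |
| outcome effects (GAD-7) | intercept −2.07; log-review 0.23; interaction −0.02; initial 0.16 | |
| noise / therapist / organization SD | 1.0 / 0.4 / 0.2 | cube-root-change scale |

Counts are truncated rounded Gaussians — the simplest family matching the
stated first two moments. Initial scores are integer draws (PHQ-9
N(12.2, 5.7) in [1, 27]; GAD-7 N(11.1, 4.8) in [1, 21]) with a shared gate
ensuring at least one instrument starts ≥5 except for planted violators;
80% of clients carry both instruments.

Text is rendered from template banks with **disjoint topic vocabularies**:
activity phrases (setting + activity noun + "routine") for recommendations
and their reviews, upcoming-event nouns for client-initiated future plans,
and past/present-focused topics for filler. Each backbone position offers
several phrasing variants so that two recommendation dialogues share topic
words, not boilerplate — this is what anchors TF-IDF similarity on content.
A client's recommended activities cycle through a per-client permutation of
60 nouns, so consecutive sessions never repeat an activity and each review
is lexically tied to exactly one prior recommendation. Every rendered
micro-dialogue totals 300–320 words with all proper prefixes under 300,
which makes greedy 300-word segmentation recover the planted boundaries
exactly; detector evaluation against latent labels is therefore exact
rather than approximate.

Planted inclusion-rule violations (short session, sparse session, bad
assessment window, sub-threshold scores, session spacing) are assigned to
*disjoint* client subsets so exclusion counts can be audited one-to-one
against the logs.

### Outcome generation and the recovery design

The outcome is generated directly on the cube-root-change scale:

```
change^{1/3} = β₀ + β_r·x̄ + β_i·initial + β_x·x̄·initial
             + β_d·dialogues + β_p·prior recs + β_t·days
             + therapist effect + ε,     x̄ = client mean of log(1+review%)
```

and the final score is recovered by inverting the change formula, then
clipping to the instrument range (clip events are counted; they are rare
under the defaults, ~1%).

One structural point drives two generator switches. In the fitted GEE the
outcome is constant within client while the regressor varies across
sessions. If the data-generating exposure is the client's *mean* transformed
review percentage but sessions fluctuate around it, the session-level
regression is an errors-in-variables problem: the estimated within-cluster
correlation approaches 1 and the within-cluster regressor variation — which
carries no outcome information — dominates the estimating equations,
attenuating the coefficient severely. (The default, realistic generator
mode exhibits exactly this, and the worked example in the README shows it.)
For simulation studies whose purpose is to test the *estimator*, the
generator therefore supports:

* `constant_session_structure=True` — dialogue, recommendation and review
  counts are drawn once per client, making the regressor cluster-constant so
  the marginal estimand equals the planted coefficient exactly;
* `discretize_scores=False` — final scores stay continuous. Integer
  rounding has granularity `100/initial` on the change scale, and pushing
  that coarse noise through the concave cube root biases slopes noticeably;
  continuous scores remove it.

Under these recovery conditions (400 clients, 40 therapists, 5
organizations, ~1,500 analysis rows) the replicate studies in the test suite
show unbiased recovery of the planted 0.61 main effect and −0.02 interaction
with 95% CI coverage near nominal, and a type-I error near 0.05 under a null
review effect. The stratified-pattern study plants a positive effect
(β = 0.8) only in the mild stratum of a shallow 10-therapist hierarchy — a
deep hierarchy leaves too few clusters per dummy within strata — and checks
that the effect surfaces there and nowhere else.

## Detection and review scoring

Stage 1 (future plans) uses TF-IDF (unigram+bigram, lowercased, sublinear
tf) with a regularized logistic model; stage 2 (action recommendations among
plans) uses an online passive-aggressive max-margin learner. The decision
threshold is the sign of the margin. Training labels are sampled from the
generator's latent truth — the synthetic counterpart of expert annotation —
at the annotation-dataset sizes the protocol prescribes (1,191 stage-1 and
311 stage-2 labels, 70/30 train/validation).

Summaries are deterministic extractive stand-ins for generative models: the
recommendation summary is the therapist utterance richest in
recommendation-cue words; the general summary is the two most central
utterances by TF-IDF cosine centrality. Both sit behind small interfaces
that admit neural replacements.

Review detection embeds summaries in a corpus-level TF-IDF space and takes,
for each micro-dialogue of session *t*, the **maximum** cosine similarity
against session *t−1*'s recommendation summaries; a dialogue counts once no
matter how many recommendations it exceeds the threshold against, and zero
prior recommendations yields no reviews. The threshold is the cut
maximizing F1 over a 90-pair labeled sample of exactly this max-similarity
statistic (candidates: midpoints of consecutive distinct similarities plus
the extremes; ties to the smallest cut; "exceeds" is strict). Calibrating on
the detector's own decision statistic, rather than on arbitrary summary
pairs, keeps the threshold aligned with the deployment distribution,
including its hard negatives.

The review-percentage denominator is *all* micro-dialogues of the session,
and a recommendation-bearing dialogue may itself count as reviewing;
multi-session (t−2 and earlier) tracing is out of scope.

## What the synthetic corpus does and does not show

Passing tests demonstrate that the pipeline's machinery is correct: the
segmentation is an exact partition, the cascade and review detector recover
planted labels on lexically separable text, the inclusion filters remove
exactly what they should, and the GEE machinery is unbiased and calibrated
under its own assumptions. They do **not** show that TF-IDF detection would
reach these levels on real clinical language (the real task used fine-tuned
transformer classifiers and a pretrained sentence encoder, which the
interfaces here accept as drop-ins), nor that real outcomes follow the
planted linear model, nor anything about the direction of causality. The
generator also deliberately omits dropout, missed sessions, demographic
covariates, and any dependence between baseline severity and review
percentage (they are independent by construction — a modeling choice, not a
claim about real data).

## Problem sizes

The seeded reference text corpus uses 60 clients / 24 therapists / 6
organizations (~310 sessions, ~9,000 micro-dialogues) — large enough for
held-out detector evaluation while keeping full text rendering and TF-IDF
fitting quick. Replicate GEE studies run at the 400-client recovery
configuration (100 recovery replicates, 200 null replicates, 30 stratified
replicates); the acceptance script reports 10-replicate recovery means and a
B = 1,000 bootstrap at 150 clients. These sizes are the package's defaults
for its own studies; all are configurable.
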