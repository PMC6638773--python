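# Methods

This note documents the models and procedures `symptweet` implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Problem setting

Posts collected from a keyword-tracked social-media stream are classified
as *relevant* (the author currently shows symptoms of the target syndrome,
asthma / difficulty breathing) or *irrelevant* (news, awareness, chatter,
past events).  The daily stream of relevant posts is then a candidate
syndromic-surveillance indicator, to be compared against reference health
series such as out-of-hours GP call proportions.

## Cleaning

Cleaning runs in four ordered passes: (1) retweets (a leading "RT " or an
explicit retweet marker); (2) exact-text duplicates, keyed on the
lowercased, URL-tokenised, whitespace-collapsed text so that copies of one
post with different appended URLs collapse to one key — the earliest record
of each group survives; (3) repeated posts by one user on one UTC calendar
day beyond the first; (4) bot/news heuristics.  Duplication is removed
because repeated text inflates the daily signal without adding information.

Bot detection is necessarily heuristic.  The default rule set is a source
(client) blocklist and a per-user daily posting threshold (default 10
posts/day; exceeding it drops the user's posts that day).  A third rule —
posts that carry a URL but no first-person pronoun, typical of headline
feeds — is implemented but disabled by default, because genuine symptomatic
posts can share links and the false-positive cost is asymmetric.  All rules
are configurable (`BotRuleSet`).

Location filtering is deliberately coarse: a post is retained if any
populated geo field (timezone string, country code, coordinate bounding
box) matches the configured region.  Posts with no geo fields at all are
retained by default (most posts carry none, and the package's concern is
relevance classification, not geolocation); a switch drops them.

## Features

Tokenisation lowercases, splits words, preserves emojis (unicode pictograph
ranges), emoticons (a regex inventory of Western punctuation faces plus a
small kaomoji set) and the `<URL>` token as standalone tokens, and applies
a compact rule-based lemmatiser (irregular map + suffix rules).  Suffix
stripping is ambiguous in general, so the lemmatiser checks candidate stems
against a reference set built from the packaged lexicons; lexicon entries
pass through the same lemmatiser at load, which guarantees that inflected
corpus tokens and lexicon entries land on the same form.  This is a
deliberately small component: its contract is inflection-collapsing for the
lexicon vocabulary, not linguistic completeness.

The compound vector per post is the union of:

* n-gram term frequencies over a vocabulary built from **training texts
  only** (default unigrams + bigrams, document frequency ≥ 2; binary
  weights available by flag — with 8–25-token posts, counts and binaries
  rarely differ);
* word-class counts for five curated classes (Infection, Possession,
  Concern, Humour, Symptomatic), with multi-word members matched on token
  bigrams;
* positive and negative word counts from two sentiment dictionaries
  (words in neither dictionary are not counted);
* a *denotes-laughter* binary (laughter slang such as "lol"/"lmao",
  laughing emojis, smiling emoticons);
* a *negative-emoji/emoticon* binary (ill/sad/angry faces, e.g. the
  medical-mask emoji and the crying emoticon `:'(`).

The emoji/emoticon lists ship as editable plain-text data files and are
curated stand-ins (marked synthetic): no authoritative inventory exists,
so they cover the canonical members and are meant to be extended.

The two co-training views are overlapping projections: X₁ (taxonomical) =
n-grams + word classes + the two tone binaries; X₂ (sentimental) = n-grams
+ sentiment counts + the two tone binaries.  Their union is the full
vector.

## Learners

Five scikit-learn families sit behind one contract.  *Confidence* is the
probability of the predicted class — the natural reading of a threshold
θ ∈ (0, 1]: predicted-class posterior for NB/LR/MLP, leaf class proportion
for the decision tree, and Platt-calibrated probability for the SVM (a
margin is not a probability).  Default hyper-parameters reproduce the
tuned settings reported for the original study (LR: L2, C = 1e-5; SVM:
RBF, C = 0.01; MLP: two 128-unit layers, learning rate 0.001, α = 1e-4,
batch 200, 100 epochs, Adam); these were tuned to a real tweet corpus and
are not necessarily sensible elsewhere — the heavily regularised LR/SVM
settings collapse to majority-class prediction on the synthetic benchmark.

Class imbalance is corrected by random duplication oversampling of the
minority class to a target fraction (default 0.47) on training data only;
test and holdout data are never balanced.

## Iterative labelling

Self-training: batches (default 200) are drawn from the unlabelled pool in
stored order; an instance whose predicted-class confidence strictly
exceeds θ moves to L under its predicted label, and the learner is refit
on the grown L (optionally re-balanced each refit).  Unconfident instances
return to the pool and are revisited on the next pass; the loop stops when
the pool is exhausted, a full pass assimilates nothing, an iteration cap
is hit, or the holdout F₂ stays below its best for `patience` consecutive
iterations.  The model returned is the best-holdout-F₂ snapshot (the
initial supervised fit counts as iteration 0), matching a tuned-best
reporting protocol.  L is grow-only: pseudo-labelled instances are never
re-examined, so |L| + |U| is conserved.

Co-training maintains one learner per view.  An instance is assimilated
when **at least one** view-learner exceeds θ, under that learner's label;
if both exceed θ and disagree, the more confident view wins, and an exact
tie leaves the instance in the pool (least commitment).  Because the model
applied in practice is an all-features retrain on the grown L, an
all-features model is fit each iteration and its holdout F₂ — not the view
models' — steers the stopping rule and the returned best snapshot.  With θ
above the maximum achievable confidence both algorithms reduce exactly to
the supervised baseline.

The default `patience` is 2; the packaged benchmark runs with patience 10
and θ = 0.9 because with 200-post batches the per-iteration holdout F₂ is
noisy and a short patience stops at the first dip rather than at genuine
sustained deterioration.

## Evaluation

F₂ is the headline metric: a missed relevant post (false negative) costs
more than a retained irrelevant one, because the surveillance signal may
be weak.  Undefined ratios (no positive predictions, no positive
instances) are reported as NaN with a warning, never silently as zero;
F_β at P = R = 0 is defined as 0.  Fleiss' κ is computed from an
items × categories rater-count table (statsmodels backend) with the
degenerate single-category case reported as NaN.  Ablation removes one
named feature block at a time and reports the F₁ drop.  Informativeness
uses add-0.5 smoothing on per-class presence counts so single-class words
stay finite, and additionally reports each word's unsmoothed
occurrence-share "priors" per class.  Keyword retrieval uses logical-AND
term matching (all terms of a multi-word keyword, any order,
case-insensitive, on word boundaries).  Raw p-values are reported
throughout; no multiple-testing correction is applied across correlation
tables.

## Signal

The daily signal is the count (or within-day proportion) of relevant
posts, gap-filled with zeros.  Smoothing is a trailing 7-day moving
average (value at day *d* = mean of days *d−6 … d*; the first six values
average what is available) — trailing because surveillance systems report
retrospectively; a centred mode is available.  Correlation is Pearson's r
with a two-sided p-value on the date-intersected (by default smoothed)
series; missing reference dates are not interpolated.

## Synthetic data

Posts are bag-of-words token sequences of 8–25 tokens, not grammatical
English — sufficient for every feature and learner in scope, and the main
reason results here do not transfer quantitatively to real text.  Relevant
posts over-draw (rate 0.4) from a symptomatic vocabulary rich in
first-person and negative-sentiment words; irrelevant posts are a mixture
of casual chatter and (35%) "awareness" posts that mix symptom words with
news vocabulary — the hard case for relevance filtering.  Class-conditional
laughter and negative-emoji injection rates are chosen so the marginals
echo the observed feature distributions at a 23% relevant prior (negative
emojis in ≈ 5.5% of posts, ≈ 75% of those relevant; laughter in ≈ 3.9%).
Duplicates, retweets and source-flagged bot posts are injected at 5/5/2%
with every injection recorded, so cleaner recall is scorable exactly.

Because the emission model is known, the Bayes-optimal posterior is
computable in closed form (mixture likelihoods plus Bernoulli terms for
the two binary injections) and bounds every learner from above — a
calibration check no real corpus offers.

The paired stream draws daily relevant counts from a Poisson around a
fluctuating rate and builds the health indicator as an affine combination
of the standardised realised counts (weight ρ) and independent noise
(weight √(1−ρ²)), so the construction correlation is ρ by design and the
ρ = 1, zero-noise case is exactly affine (r = 1).  Irrelevant chatter is
overlaid with independent day-to-day fluctuation; this is what relevance
filtering removes, and why the unfiltered volume signal correlates much
worse.  No day-of-week seasonality is generated by default.

## Benchmark problem sizes

The packaged semi-supervised benchmark uses 500 labelled posts (70:30
split) and an 8000-post unlabelled pool, with logistic regression (C = 1)
as the base learner: it is well-calibrated, refits in milliseconds at this
scale, and keeps a 5-seed benchmark in the low minutes.  The MLP at its
printed settings participates in the supervised family comparison but is
not the semisup base here.

## Known limitations

* The family ordering observed on real text (MLP strongest) does not
  transfer to the synthetic fixture: the generator is a bag-of-words
  mixture, so multinomial naive Bayes is close to the true model and
  legitimately the strongest family at this training size.  The family
  comparison test asserts what holds on the fixture (MLP above DT and the
  regularised LR/SVM; everything below the Bayes bound).
* Passing tests on the generator demonstrate correctness of the machinery
  and the qualitative orderings (semisup ≥ supervised, co-training's
  assimilation quality, filtering's correlation benefit), not performance
  on real social-media text, which is noisier, drifts over time and
  violates the bag-of-words assumption.
* The lemmatiser is rule-based and lexicon-scoped; out-of-lexicon
  inflections may not collapse.
* Geolocation is coarse field matching; accurate location inference is out
  of scope.
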