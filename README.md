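# symptweet

Relevance filtering of symptomatic social-media posts for syndromic
surveillance.

Keyword-collected social-media streams are dominated by chatter, news and
awareness posts.  For a syndromic-surveillance signal (here: asthma /
difficulty breathing) only *relevant* posts matter — those announcing or
hinting that an individual currently has symptoms.  `symptweet` implements
the full filtering pipeline:

* **Cleaning** — URL tokenisation (`<URL>`), retweet and exact-duplicate
  removal, per-user same-day deduplication, bot/news heuristics, coarse
  location filtering.
* **Compound features** — each post *i* becomes a dictionary-backed vector
  *T_i* = {t_i1 … t_in} ∪ {C_i1} ∪ {C_i2} ∪ {C_i3} ∪ {C_i4}: word-level
  n-gram counts over a training-set vocabulary plus four custom groups
  (word-class counts; positive/negative word counts; a *denotes-laughter*
  binary; a *negative-emoji/emoticon* binary).
* **Learners** — naive Bayes, decision tree, logistic regression, RBF SVM
  and MLP behind one fit / predict / confidence contract, with random
  duplication oversampling for class imbalance and grid search on a
  held-out slice.
* **Semi-supervised labelling** — confidence-based **self-training**
  (assimilate an unlabelled post into L when the classifier's confidence
  exceeds θ, refit, repeat) and two-view **co-training** (one learner on
  the taxonomical view X₁ = n-grams + word classes + tone binaries, one on
  the sentimental view X₂ = n-grams + sentiment counts + tone binaries; a
  post is assimilated when either view is confident, and an all-features
  model is what gets applied in practice).
* **Evaluation** — precision/recall/accuracy, F_β = (1+β²)PR/(β²P+R) with
  F₂ as the headline metric (recall weighted double: losing a relevant
  post costs more than keeping an irrelevant one), Fleiss' κ for
  inter-rater agreement, feature ablation, word informativeness
  I = max_c P(w|c) / min_c P(w|c), and keyword retrieval assessment.
* **Signal** — daily proportion/count of relevant posts, 7-day moving
  average, Pearson correlation against a reference health-indicator
  series (e.g. daily out-of-hours GP call proportions).
* **Synthetic data** — a generator with recorded ground truth (class
  prior ≈ 23% relevant, negative emojis in ≈ 5.5% of posts and heavily
  concentrated in the relevant class, duplicate/retweet/bot contamination,
  paired stream/health-series with a controllable correlation), plus a
  closed-form Bayes-optimal reference classifier.

No real social-media or health-service data ships with the package; every
analysis runs on the synthetic fixtures.

## Worked example

`examples/03_semi_supervised.py` runs the packaged benchmark — 500
labelled posts (70:30 split, training balanced to 47% relevant by
oversampling) against an 8000-post unlabelled pool, logistic-regression
base learner, θ = 0.9, batches of 200:

```
labelled posts: 500  unlabelled pool: 8000
supervised baseline F2 : 0.932
self-training F2       : 0.976
co-training F2         : 0.976
assimilation correct (self): 0.982
assimilation correct (co)  : 0.975
```

The supervised baseline is what 350 labelled training posts alone support.
Self-training and co-training both lift F₂ by pseudo-labelling confident
unlabelled posts; the assimilation-correct lines report the fraction of
those pseudo-labels that match the (withheld) truth.  The other examples
cover cleaning and featurisation (`01`), the supervised families plus
ablation/informativeness/keyword analyses (`02`), and the daily
surveillance signal, where relevance filtering raises the correlation with
the paired health series from r = 0.31 to r = 0.41 on a stream built at
ρ = 0.4 (`04`).

A thin CLI wraps the same calls:

```bash
symptweet simulate corpus --n 1000 --seed 7 --out fixtures/
symptweet clean --in fixtures/corpus.jsonl --out clean.jsonl
symptweet run --corpus fixtures/corpus.jsonl --labels labels.csv --method cotrain --seed 7
```

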