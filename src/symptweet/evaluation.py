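"""Evaluation: confusion matrices, precision/recall/F-beta, Fleiss' kappa,
feature ablation, word informativeness and keyword retrieval assessment.

The positive class throughout is "relevant" (a post announcing current
symptoms).  F2 — recall weighted twice as heavily as precision — is the
primary model-selection metric, because losing a relevant post costs more
than keeping an irrelevant one when the surveillance signal is weak.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from . import features as F
from .learners import RELEVANT, LearnerSpec, fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: Sequence[str], truth: Sequence[str], positive: str = RELEVANT) -> ConfusionMatrix:
    """Count the four confusion cells with ``positive`` as the positive class."""
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    tp = fp = fn = tn = 0
    for p, t in zip(pred, truth):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def prf_accuracy(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(precision, recall, accuracy).  An undefined ratio (zero denominator)
    is returned as NaN with a warning, never silently as 0."""
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        logger.warning("precision undefined: no positive predictions")
        precision = float("nan")
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        logger.warning("recall undefined: no positive instances")
        recall = float("nan")
    accuracy = (cm.tp + cm.tn) / cm.total if cm.total else float("nan")
    return precision, recall, accuracy


def f_beta(precision: float, recall: float, beta: float = 2.0) -> float:
    """F-beta = (1+b^2) P R / (b^2 P + R); defined as 0 when P = R = 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if precision == 0 and recall == 0:
        logger.warning("F-beta undefined at P=R=0; returning 0")
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def f2_score(pred: Sequence[str], truth: Sequence[str]) -> float:
    """Convenience: F2 of a prediction vector against truth."""
    p, r, _ = prf_accuracy(confusion(pred, truth))
    if not (np.isfinite(p) and np.isfinite(r)):
        return 0.0
    return f_beta(p, r, 2.0)


# ---------------------------------------------------------------------------
# Inter-rater agreement.
# ---------------------------------------------------------------------------


def fleiss_kappa(ratings: Sequence[Sequence[int]]) -> float:
    """Fleiss' kappa from an items x categories table of rater counts.

    kappa = (P_bar - P_e) / (1 - P_e), with chance agreement P_e from the
    observed category marginals.  Returns NaN (degenerate) when every rating
    falls in one category, i.e. P_e = 1.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("ratings must be a 2-D items x categories table")
    n_raters = table.sum(axis=1)
    if not np.all(n_raters == n_raters[0]):
        raise ValueError("each item must have the same number of ratings")
    marginals = table.sum(axis=0) / table.sum()
    if np.max(marginals) == 1.0:
        logger.warning("kappa degenerate: a single category holds all ratings")
        return float("nan")
    return float(_sm_fleiss_kappa(table, method="fleiss"))


# ---------------------------------------------------------------------------
# Feature ablation.
# ---------------------------------------------------------------------------

ABLATION_BLOCKS = ("ngrams", "word_classes", "posneg_counts", "denotes_laughter", "negative_emoji")


def ablation(
    X_train: Sequence[Mapping[str, float]],
    y_train: Sequence[str],
    X_test: Sequence[Mapping[str, float]],
    y_test: Sequence[str],
    spec: LearnerSpec,
    blocks: Sequence[str] = ABLATION_BLOCKS,
) -> pd.DataFrame:
    """F1 with all features minus F1 with each block removed.

    Returns a DataFrame with rows "None" (baseline, delta 0) and one per
    ablated block; a positive delta means the block helped.
    """
    def f1_of(Xtr, Xte):
        model = fit(spec, Xtr, y_train)
        p, r, _ = prf_accuracy(confusion(model.predict(Xte), y_test))
        if not (np.isfinite(p) and np.isfinite(r)):
            return 0.0
        return f_beta(p, r, 1.0)

    baseline = f1_of(X_train, X_test)
    rows = [{"ablated": "None", "f1": baseline, "delta_f1": 0.0}]
    for block in blocks:
        Xtr = [F.drop_block(v, block) for v in X_train]
        Xte = [F.drop_block(v, block) for v in X_test]
        if all(len(v) == 0 for v in Xtr):
            raise ValueError(f"ablating {block!r} removes every feature")
        f1 = f1_of(Xtr, Xte)
        rows.append({"ablated": block, "f1": f1, "delta_f1": baseline - f1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Word informativeness.
# ---------------------------------------------------------------------------


def informativeness(
    token_lists: Sequence[Sequence[str]],
    labels: Sequence[str],
    smoothing: float = 0.5,
) -> pd.DataFrame:
    """Rank unigrams by I = max_c P(w present | c) / min_c P(w present | c).

    Per-class presence probabilities use additive smoothing so single-class
    words stay finite.  Also reports each word's occurrence-share "priors":
    the fraction of posts containing the word that fall in each class
    (unsmoothed), the form the study's informative-word tables print.
    """
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("informativeness needs both classes present")
    n_by_class = {c: labels.count(c) for c in classes}

    presence: dict[str, dict[str, int]] = {}
    for tokens, lbl in zip(token_lists, labels):
        for w in set(tokens):
            presence.setdefault(w, {c: 0 for c in classes})[lbl] += 1

    rows = []
    for w, counts in presence.items():
        probs = {
            c: (counts[c] + smoothing) / (n_by_class[c] + 2 * smoothing) for c in classes
        }
        hi = max(classes, key=lambda c: probs[c])
        lo = min(classes, key=lambda c: probs[c])
        total_occ = sum(counts.values())
        rows.append(
            {
                "word": w,
                "I": probs[hi] / probs[lo],
                "majority_class": hi,
                "n_relevant": counts.get(RELEVANT, 0),
                "n_irrelevant": total_occ - counts.get(RELEVANT, 0),
                "prior_relevant": counts.get(RELEVANT, 0) / total_occ,
                "prior_irrelevant": 1 - counts.get(RELEVANT, 0) / total_occ,
            }
        )
    df = pd.DataFrame(rows).sort_values(["I", "word"], ascending=[False, True])
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Keyword information-retrieval assessment.
# ---------------------------------------------------------------------------


def keyword_ir(
    keywords: Sequence[str],
    texts: Sequence[str],
    labels: Sequence[str],
) -> pd.DataFrame:
    """Per-keyword retrieval precision and recall over a labelled corpus.

    A post matches a (possibly multi-word) keyword when it contains all of
    the keyword's terms, case-insensitively, in any order — the logical-AND
    semantics of streaming-API track phrases.  A keyword matching nothing
    reports precision 0.000 with n_matched 0.
    """
    labels = list(labels)
    n_relevant = sum(1 for l in labels if l == RELEVANT)
    lowered = [t.lower() for t in texts]
    rows = []
    for kw in keywords:
        terms = [re.escape(t) for t in kw.lower().split()]
        pats = [re.compile(r"(?<!\w)" + t + r"(?!\w)") for t in terms]
        matched = [i for i, txt in enumerate(lowered) if all(p.search(txt) for p in pats)]
        rel_matched = sum(1 for i in matched if labels[i] == RELEVANT)
        precision = rel_matched / len(matched) if matched else 0.0
        recall = rel_matched / n_relevant if n_relevant else 0.0
        rows.append(
            {"keyword": kw, "precision": precision, "recall": recall, "n_matched": len(matched)}
        )
    return pd.DataFrame(rows)
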