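"""Confidence-based iterative labelling: self-training and co-training.

Both algorithms grow a labelled set L from an unlabelled pool U.  Batches of
unlabelled posts are drawn in stored order; an instance is assimilated —
moved from U to L under its predicted label — when the classifier's
confidence exceeds a threshold theta, and the classifier is refit on the
grown L.  Iteration stops when U is exhausted, when a pass assimilates
nothing, or when the held-out F2 deteriorates for ``patience`` consecutive
iterations.

Self-training uses one learner on the full feature vector.  Co-training
maintains two learners on the taxonomical and sentimental views; an
instance is assimilated when at least one view-learner is confident, taking
that learner's label (ties between disagreeing, equally confident views
leave the instance in U).  On termination, all labelled instances train one
final learner on all features, which is what gets applied in practice.

Pseudo-labelled instances are never re-examined or relabelled: L is
grow-only, so |L| + |U| is conserved at every iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import build_views
from .learners import LearnerModel, LearnerSpec, fit, oversample


@dataclass(frozen=True)
class IterLabelConfig:
    """Knobs of the iterative-labelling loop.

    theta: confidence threshold in (0, 1] an instance must exceed (strictly)
        to be assimilated.
    batch_size: unlabelled instances drawn per iteration (default 200).
    patience: consecutive holdout-F2-deteriorating iterations tolerated.
    max_iterations: hard cap on iterations (None = unlimited).
    balance_fraction: if set, each refit first oversamples the minority
        class of the current L to this fraction (training-time balancing;
        holdout and test data are never balanced).
    shuffle: draw U in a seeded random order instead of stored order.
    """

    theta: float = 0.8
    batch_size: int = 200
    patience: int = 2
    max_iterations: int | None = None
    seed: int = 0
    balance_fraction: float | None = None
    shuffle: bool = False

    def __post_init__(self):
        if not (0 < self.theta <= 1):
            raise ValueError("theta must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class IterLabelTrace:
    """Per-iteration record of the labelling process."""

    rows: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        self.rows.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @property
    def n_assimilated_total(self) -> int:
        return sum(r["n_assimilated"] for r in self.rows)

    def conserves_mass(self) -> bool:
        """|L| + |U| constant and |L| non-decreasing across iterations."""
        totals = {r["n_labelled"] + r["n_unlabelled"] for r in self.rows}
        sizes = [r["n_labelled"] for r in self.rows]
        return len(totals) <= 1 and all(a <= b for a, b in zip(sizes, sizes[1:]))


def _check_disjoint(holdout, *pools) -> None:
    hold_ids = {id(x) for x in holdout}
    for pool in pools:
        if any(id(x) in hold_ids for x in pool):
            raise ValueError("holdout overlaps the labelled or unlabelled pool")


def _balanced_fit(
    spec: LearnerSpec,
    X: Sequence[Mapping[str, float]],
    y: Sequence[str],
    cfg: IterLabelConfig,
    project: Callable | None = None,
) -> LearnerModel:
    if project is not None:
        X = [project(x) for x in X]
    if cfg.balance_fraction is not None:
        X, y = oversample(X, y, cfg.balance_fraction, seed=cfg.seed)
    return fit(spec, X, y)


def supervised_baseline(
    X_l: Sequence[Mapping[str, float]],
    y_l: Sequence[str],
    spec: LearnerSpec,
    cfg: IterLabelConfig,
) -> LearnerModel:
    """The purely supervised model both algorithms reduce to when theta is
    unreachable: one (optionally balanced) fit on the original L."""
    return _balanced_fit(spec, X_l, y_l, cfg)


def _holdout_f2(model_predict, X_h, y_h) -> float:
    from .evaluation import f2_score

    if not len(X_h):
        return float("nan")
    return f2_score(model_predict(X_h), y_h)


def _draw_order(n: int, cfg: IterLabelConfig) -> list[int]:
    order = list(range(n))
    if cfg.shuffle:
        rng = np.random.default_rng(cfg.seed)
        rng.shuffle(order)
    return order


def self_train(
    X_l: Sequence[Mapping[str, float]],
    y_l: Sequence[str],
    X_u: Sequence[Mapping[str, float]],
    spec: LearnerSpec,
    cfg: IterLabelConfig,
    X_holdout: Sequence[Mapping[str, float]] = (),
    y_holdout: Sequence[str] = (),
    y_u_true: Sequence[str] | None = None,
) -> tuple[LearnerModel, IterLabelTrace]:
    """Confidence-based self-training.

    Returns the model from the best-holdout-F2 iteration (the supervised
    fit counts as iteration 0) and the full trace.  ``y_u_true``, if given,
    is used only to score assimilation correctness in the trace.
    """
    if not len(X_l) or len(set(y_l)) < 2:
        raise ValueError("L must be non-empty with both classes")
    _check_disjoint(X_holdout, X_l, X_u)

    L_X, L_y = list(X_l), list(y_l)
    queue = _draw_order(len(X_u), cfg)
    trace = IterLabelTrace()

    model = _balanced_fit(spec, L_X, L_y, cfg)
    f2 = _holdout_f2(model.predict, X_holdout, y_holdout)
    best_model, best_f2 = model, f2
    trace.append(
        iteration=0, n_assimilated=0, n_correct=0,
        holdout_f2=f2, n_labelled=len(L_X), n_unlabelled=len(queue),
    )

    iteration = 0
    bad_streak = 0
    deferred: list[int] = []
    assimilated_this_pass = 0
    while queue:
        if cfg.max_iterations is not None and iteration >= cfg.max_iterations:
            break
        iteration += 1
        batch, queue = queue[: cfg.batch_size], queue[cfg.batch_size :]
        labels, conf = model.predict_with_confidence([X_u[i] for i in batch])
        n_assim = n_correct = 0
        for j, i in enumerate(batch):
            if conf[j] > cfg.theta:
                L_X.append(X_u[i])
                L_y.append(str(labels[j]))
                n_assim += 1
                if y_u_true is not None and labels[j] == y_u_true[i]:
                    n_correct += 1
            else:
                deferred.append(i)
        assimilated_this_pass += n_assim
        if n_assim:
            model = _balanced_fit(spec, L_X, L_y, cfg)
        f2 = _holdout_f2(model.predict, X_holdout, y_holdout)
        trace.append(
            iteration=iteration, n_assimilated=n_assim, n_correct=n_correct,
            holdout_f2=f2, n_labelled=len(L_X), n_unlabelled=len(queue) + len(deferred),
        )
        if not math.isnan(f2) and (math.isnan(best_f2) or f2 > best_f2):
            best_model, best_f2 = model, f2
            bad_streak = 0
        elif not math.isnan(f2) and f2 < best_f2:
            bad_streak += 1
            if bad_streak >= cfg.patience:
                break
        else:
            bad_streak = 0
        if not queue:  # end of a pass over U: revisit deferred only on progress
            if assimilated_this_pass and deferred:
                queue, deferred = deferred, []
                assimilated_this_pass = 0
            else:
                break
    return best_model, trace


def co_train(
    X_l: Sequence[Mapping[str, float]],
    y_l: Sequence[str],
    X_u: Sequence[Mapping[str, float]],
    spec: LearnerSpec,
    cfg: IterLabelConfig,
    X_holdout: Sequence[Mapping[str, float]] = (),
    y_holdout: Sequence[str] = (),
    y_u_true: Sequence[str] | None = None,
) -> tuple[LearnerModel, IterLabelTrace]:
    """Two-view co-training.

    One learner per view (taxonomical / sentimental); an instance is
    assimilated when at least one view-learner's confidence exceeds theta,
    under that learner's label (the more confident view wins disagreements;
    exact ties stay in U).  Each iteration the grown labelled set also
    trains an all-features model — the one applied in practice — whose
    holdout F2 steers stopping; the best such snapshot is returned with the
    trace.
    """
    if not len(X_l) or len(set(y_l)) < 2:
        raise ValueError("L must be non-empty with both classes")
    _check_disjoint(X_holdout, X_l, X_u)

    view1 = lambda x: build_views(x)[0]
    view2 = lambda x: build_views(x)[1]

    L_X, L_y = list(X_l), list(y_l)
    queue = _draw_order(len(X_u), cfg)
    trace = IterLabelTrace()

    m1 = _balanced_fit(spec, L_X, L_y, cfg, project=view1)
    m2 = _balanced_fit(spec, L_X, L_y, cfg, project=view2)
    # The model applied in practice is the all-features retrain, so the
    # stopping rule and best-snapshot tracking are steered by its holdout
    # F2, not the view-learners'.
    combined = _balanced_fit(spec, L_X, L_y, cfg)
    f2 = _holdout_f2(combined.predict, X_holdout, y_holdout)
    best_f2 = f2
    best_model = combined
    trace.append(
        iteration=0, n_assimilated=0, n_correct=0,
        holdout_f2=f2, n_labelled=len(L_X), n_unlabelled=len(queue),
    )

    iteration = 0
    bad_streak = 0
    deferred: list[int] = []
    assimilated_this_pass = 0
    while queue:
        if cfg.max_iterations is not None and iteration >= cfg.max_iterations:
            break
        iteration += 1
        batch, queue = queue[: cfg.batch_size], queue[cfg.batch_size :]
        batch_x = [X_u[i] for i in batch]
        lab1, conf1 = m1.predict_with_confidence([view1(x) for x in batch_x])
        lab2, conf2 = m2.predict_with_confidence([view2(x) for x in batch_x])
        n_assim = n_correct = 0
        for j, i in enumerate(batch):
            c1_ok, c2_ok = conf1[j] > cfg.theta, conf2[j] > cfg.theta
            if not (c1_ok or c2_ok):
                deferred.append(i)
                continue
            if c1_ok and c2_ok and lab1[j] != lab2[j] and conf1[j] == conf2[j]:
                deferred.append(i)  # least-commitment: equally confident disagreement
                continue
            if c1_ok and (not c2_ok or conf1[j] >= conf2[j]):
                label = str(lab1[j])
            else:
                label = str(lab2[j])
            L_X.append(X_u[i])
            L_y.append(label)
            n_assim += 1
            if y_u_true is not None and label == y_u_true[i]:
                n_correct += 1
        assimilated_this_pass += n_assim
        if n_assim:
            m1 = _balanced_fit(spec, L_X, L_y, cfg, project=view1)
            m2 = _balanced_fit(spec, L_X, L_y, cfg, project=view2)
            combined = _balanced_fit(spec, L_X, L_y, cfg)
        f2 = _holdout_f2(combined.predict, X_holdout, y_holdout)
        trace.append(
            iteration=iteration, n_assimilated=n_assim, n_correct=n_correct,
            holdout_f2=f2, n_labelled=len(L_X), n_unlabelled=len(queue) + len(deferred),
        )
        if not math.isnan(f2) and (math.isnan(best_f2) or f2 > best_f2):
            best_f2 = f2
            best_model = combined
            bad_streak = 0
        elif not math.isnan(f2) and f2 < best_f2:
            bad_streak += 1
            if bad_streak >= cfg.patience:
                break
        else:
            bad_streak = 0
        if not queue:
            if assimilated_this_pass and deferred:
                queue, deferred = deferred, []
                assimilated_this_pass = 0
            else:
                break

    return best_model, trace


def assimilation_quality(
    X_l: Sequence[Mapping[str, float]],
    y_l: Sequence[str],
    X_pseudo: Sequence[Mapping[str, float]],
    y_pseudo_true: Sequence[str],
    spec: LearnerSpec,
    cfg: IterLabelConfig,
    method: str = "self",
) -> pd.DataFrame:
    """Run iterative labelling against a pool whose true labels are known
    but withheld, and report the per-step fraction of assimilated instances
    whose pseudo-label matched the hidden truth."""
    runner = {"self": self_train, "co": co_train}[method]
    _, trace = runner(X_l, y_l, X_pseudo, spec, cfg, y_u_true=list(y_pseudo_true))
    df = trace.to_dataframe()
    df = df[df["iteration"] > 0].copy()
    df["proportion_correct"] = np.where(
        df["n_assimilated"] > 0, df["n_correct"] / df["n_assimilated"], np.nan
    )
    return df[["iteration", "n_assimilated", "n_correct", "proportion_correct"]]


@dataclass(frozen=True)
class PairedComparison:
    t_statistic: float
    p_value: float
    degenerate: bool = False


def compare_models_paired(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> PairedComparison:
    """Two-sided paired t-test on per-resample score differences.

    Identical vectors give (t=0, p=1).  A non-zero constant difference has
    zero variance, so no p-value is defined: reported as degenerate.
    """
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired scores")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return PairedComparison(0.0, 1.0, degenerate=False)
        return PairedComparison(math.inf if d.mean() > 0 else -math.inf, float("nan"), True)
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(float(t), float(p), False)
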