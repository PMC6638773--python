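"""Metrics, Fleiss' kappa, ablation, informativeness and keyword IR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptweet.evaluation import (
    ConfusionMatrix,
    ablation,
    confusion,
    f_beta,
    fleiss_kappa,
    informativeness,
    keyword_ir,
    prf_accuracy,
)
from symptweet.learners import IRRELEVANT, RELEVANT, LearnerSpec


def _vectors_from_counts(tp, fp, fn, tn):
    pred = [RELEVANT] * (tp + fp) + [IRRELEVANT] * (fn + tn)
    truth = [RELEVANT] * tp + [IRRELEVANT] * fp + [RELEVANT] * fn + [IRRELEVANT] * tn
    return pred, truth


class TestConfusion:
    def test_perfect_prediction(self):
        pred, truth = _vectors_from_counts(6, 0, 0, 4)
        cm = confusion(pred, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (6, 0, 0, 4)

    def test_complement_prediction(self):
        truth = [RELEVANT] * 3 + [IRRELEVANT] * 3
        pred = [IRRELEVANT] * 3 + [RELEVANT] * 3
        cm = confusion(pred, truth)
        assert cm.tp == 0 and cm.tn == 0 and cm.fp == 3 and cm.fn == 3

    def test_published_cotraining_confusion(self):
        # 1202 test predictions with 274/37/17/874 cells
        pred, truth = _vectors_from_counts(274, 37, 17, 874)
        cm = confusion(pred, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (274, 37, 17, 874)
        p, r, acc = prf_accuracy(cm)
        assert round(p, 3) == 0.881
        assert round(r, 3) == 0.942
        assert round(100 * acc, 1) == 95.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([RELEVANT], [RELEVANT, IRRELEVANT])

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            pred = rng.choice([RELEVANT, IRRELEVANT], size=50)
            truth = rng.choice([RELEVANT, IRRELEVANT], size=50)
            cm = confusion(list(pred), list(truth))
            assert cm.tp == int(np.sum((pred == RELEVANT) & (truth == RELEVANT)))
            assert cm.fp == int(np.sum((pred == RELEVANT) & (truth == IRRELEVANT)))
            assert cm.fn == int(np.sum((pred == IRRELEVANT) & (truth == RELEVANT)))
            assert cm.tn == int(np.sum((pred == IRRELEVANT) & (truth == IRRELEVANT)))


class TestPrfAccuracy:
    def test_trivial_perfect(self):
        p, r, acc = prf_accuracy(ConfusionMatrix(1, 0, 0, 1))
        assert (p, r, acc) == (1.0, 1.0, 1.0)

    def test_undefined_precision_is_nan(self):
        p, _, _ = prf_accuracy(ConfusionMatrix(0, 0, 5, 5))
        assert np.isnan(p)


class TestFBeta:
    @pytest.mark.parametrize(
        "p,r,beta,expected",
        [
            (0.928, 0.878, 2, 0.888),   # strongest supervised row
            (0.839, 1.000, 2, 0.963),   # semi-supervised minority-class row
            (0.897, 0.924, 2, 0.919),
            (0.881, 0.942, 2, 0.929),
            (0.636, 0.804, 1, 0.710),
            (0.928, 0.878, 1, 0.902),
        ],
    )
    def test_published_scores_reproduced(self, p, r, beta, expected):
        assert f_beta(p, r, beta) == pytest.approx(expected, abs=2e-3)

    def test_symmetry_at_equal_pr(self):
        for p in (0.1, 0.5, 0.9):
            for beta in (0.5, 1, 2):
                assert f_beta(p, p, beta) == pytest.approx(p)

    def test_zero_zero_defined_as_zero(self):
        assert f_beta(0.0, 0.0, 2) == 0.0

    def test_f1_is_harmonic_mean(self):
        p, r = 0.6, 0.9
        assert f_beta(p, r, 1) == pytest.approx(2 / (1 / p + 1 / r))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_f2_rewards_recall(self, a, b):
        # of the two orderings of (a, b), F2 prefers the one where recall
        # holds the larger value; F1 is indifferent
        lo, hi = min(a, b), max(a, b)
        assert f_beta(lo, hi, 2) >= f_beta(hi, lo, 2) - 1e-12
        assert f_beta(lo, hi, 1) == pytest.approx(f_beta(hi, lo, 1))


def _kappa_hand(table):
    """Independent hand application of the kappa formula."""
    table = np.asarray(table, float)
    N, k = table.shape
    n = table.sum(axis=1)[0]
    p_j = table.sum(axis=0) / (N * n)
    P_i = ((table**2).sum(axis=1) - n) / (n * (n - 1))
    P_bar = P_i.mean()
    P_e = (p_j**2).sum()
    return (P_bar - P_e) / (1 - P_e)


class TestFleissKappa:
    def test_complete_agreement(self):
        table = [[3, 0], [0, 3], [3, 0], [0, 3]]
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_chance_level_agreement(self):
        # half the items in full agreement, half in full disagreement,
        # symmetric marginals: P_bar = P_e = 0.5 -> kappa = 0
        table = [[2, 0], [0, 2], [1, 1], [1, 1]]
        assert fleiss_kappa(table) == pytest.approx(0.0)

    def test_hand_worked_table(self):
        table = [[2, 1, 0], [0, 3, 0], [1, 1, 1], [0, 0, 3]]
        assert fleiss_kappa(table) == pytest.approx(_kappa_hand(table))

    def test_degenerate_single_category(self):
        assert np.isnan(fleiss_kappa([[3, 0], [3, 0]]))

    def test_invariant_to_category_relabelling_and_item_order(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            table = rng.multinomial(3, [0.5, 0.3, 0.2], size=8)
            k0 = fleiss_kappa(table)
            assert fleiss_kappa(table[:, ::-1]) == pytest.approx(k0)
            assert fleiss_kappa(table[::-1, :]) == pytest.approx(k0)

    def test_uneven_rater_counts_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa([[2, 1], [1, 1]])


class TestAblation:
    def _planted_negemoji_corpus(self, n=400, seed=2):
        """Class determined solely by the negative-emoji binary; every
        other feature is class-independent noise."""
        rng = np.random.default_rng(seed)
        X, y = [], []
        for _ in range(n):
            label = RELEVANT if rng.random() < 0.4 else IRRELEVANT
            vec = {
                "ng:asthma": float(rng.integers(0, 3)),
                "wc:Concern": float(rng.integers(0, 2)),
                "sent:pos": float(rng.integers(0, 2)),
                "sent:neg": float(rng.integers(0, 2)),
                "tone:laughter": 0.0,
                "tone:negemoji": 1.0 if label == RELEVANT else 0.0,
            }
            X.append(vec)
            y.append(label)
        return X, y

    def test_signal_block_has_largest_delta(self):
        X, y = self._planted_negemoji_corpus()
        spec = LearnerSpec("logistic_regression", {"C": 1.0}, seed=0)
        df = ablation(X[:300], y[:300], X[300:], y[300:], spec).set_index("ablated")
        deltas = df["delta_f1"].drop("None")
        assert deltas.idxmax() == "negative_emoji"
        assert df.loc["None", "delta_f1"] == 0.0

    def test_constant_zero_block_no_effect(self):
        X, y = self._planted_negemoji_corpus()
        spec = LearnerSpec("logistic_regression", {"C": 1.0}, seed=0)
        df = ablation(X[:300], y[:300], X[300:], y[300:], spec, blocks=["denotes_laughter"])
        assert abs(df.set_index("ablated").loc["denotes_laughter", "delta_f1"]) < 0.02


class TestInformativeness:
    def test_balanced_word_ratio_one(self):
        token_lists = [["even"], ["even"], ["even"], ["even"]]
        labels = [RELEVANT, RELEVANT, IRRELEVANT, IRRELEVANT]
        df = informativeness(token_lists, labels)
        assert df.loc[df.word == "even", "I"].iloc[0] == pytest.approx(1.0)

    def test_occurrence_share_priors(self):
        # a word in 24 relevant and 1 irrelevant post: priors 0.96 / 0.04
        token_lists = [["chest"]] * 25 + [["filler"]] * 25
        labels = [RELEVANT] * 24 + [IRRELEVANT] + [IRRELEVANT] * 25
        df = informativeness(token_lists, labels).set_index("word")
        assert df.loc["chest", "prior_relevant"] == pytest.approx(0.96)
        assert df.loc["chest", "prior_irrelevant"] == pytest.approx(0.04)

    def test_matches_brute_force_ratio(self):
        rng = np.random.default_rng(8)
        words = [f"w{i}" for i in range(30)]
        token_lists, labels = [], []
        for _ in range(120):
            lbl = RELEVANT if rng.random() < 0.4 else IRRELEVANT
            token_lists.append(list(rng.choice(words, size=6)))
            labels.append(lbl)
        df = informativeness(token_lists, labels).set_index("word")
        n_rel = labels.count(RELEVANT)
        n_irr = labels.count(IRRELEVANT)
        for w in words:
            in_rel = sum(1 for t, l in zip(token_lists, labels) if l == RELEVANT and w in t)
            in_irr = sum(1 for t, l in zip(token_lists, labels) if l == IRRELEVANT and w in t)
            if in_rel + in_irr == 0:
                assert w not in df.index
                continue
            p_rel = (in_rel + 0.5) / (n_rel + 1)
            p_irr = (in_irr + 0.5) / (n_irr + 1)
            expect = max(p_rel, p_irr) / min(p_rel, p_irr)
            assert df.loc[w, "I"] == pytest.approx(expect)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            informativeness([["a"]], [RELEVANT])


class TestKeywordIR:
    texts = [
        "my asthma is bad",
        "asthma awareness week",
        "air pollution report",
        "wheezing all night",
    ]
    labels = [RELEVANT, IRRELEVANT, IRRELEVANT, RELEVANT]

    def test_keyword_matching_everything(self):
        df = keyword_ir(["a"], ["a x", "a y"], [RELEVANT, IRRELEVANT]).iloc[0]
        assert df.recall == 1.0 and df.precision == 0.5

    def test_keyword_matching_nothing(self):
        df = keyword_ir(["poor air quality"], self.texts, self.labels).iloc[0]
        assert (df.precision, df.recall, df.n_matched) == (0.0, 0.0, 0)

    def test_multiword_and_semantics(self):
        # both terms must appear, order-free
        df = keyword_ir(["pollution air"], self.texts, self.labels).iloc[0]
        assert df.n_matched == 1 and df.precision == 0.0

    def test_matches_brute_force_retrieval(self):
        rng = np.random.default_rng(9)
        vocab = ["asthma", "wheeze", "pollution", "news", "chest", "lol"]
        texts, labels = [], []
        for _ in range(40):
            texts.append(" ".join(rng.choice(vocab, size=4)))
            labels.append(RELEVANT if rng.random() < 0.4 else IRRELEVANT)
        n_rel = labels.count(RELEVANT)
        df = keyword_ir(vocab, texts, labels).set_index("keyword")
        for kw in vocab:
            matched = [i for i, t in enumerate(texts) if kw in t.split()]
            rel = sum(1 for i in matched if labels[i] == RELEVANT)
            assert df.loc[kw, "n_matched"] == len(matched)
            if matched:
                assert df.loc[kw, "precision"] == pytest.approx(rel / len(matched))
            assert df.loc[kw, "recall"] == pytest.approx(rel / n_rel)

    def test_recall_sum_not_bounded_by_one(self):
        # overlapping keywords: summed recall may exceed 1 (non-constraint)
        df = keyword_ir(["asthma", "my", "wheezing"], self.texts, self.labels)
        assert df.recall.sum() >= 1.0
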