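"""Shared fixtures: lexicons, small synthetic corpora, and one session-wide
run of the semi-supervised benchmark (it is the most expensive computation
in the suite, and several tests score different aspects of the same runs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pytest

from symptweet.benchmark import BENCH_CFG, BENCH_SPEC, _prepare
from symptweet.evaluation import f2_score
from symptweet.lexicons import load_lexicons
from symptweet.semisup import IterLabelConfig, co_train, self_train, supervised_baseline
from symptweet.synthetic import CorpusSpec, generate_corpus

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def lexicons():
    return load_lexicons()


@pytest.fixture(scope="session")
def small_corpus():
    """200-post corpus with duplicate/retweet/bot/URL contamination."""
    return generate_corpus(CorpusSpec(n_tweets=200, seed=20150923))


@dataclass
class BenchmarkRun:
    seed: int
    supervised_f2: float
    self_f2: float
    co_f2: float
    self_trace: object
    co_trace: object

    def assim_correct(self, which: str) -> float:
        trace = self.self_trace if which == "self" else self.co_trace
        n_a = sum(r["n_assimilated"] for r in trace.rows)
        n_c = sum(r["n_correct"] for r in trace.rows)
        return n_c / n_a if n_a else float("nan")


@pytest.fixture(scope="session")
def benchmark_runs():
    """Self-training and co-training vs the supervised baseline on the
    packaged semisup benchmark, over 5 seeds."""
    runs = []
    for seed in range(5):
        X_train, y_train, X_test, y_test, X_u, y_u = _prepare(seed)
        spec = BENCH_SPEC.with_seed(seed)
        cfg = IterLabelConfig(seed=seed, **BENCH_CFG)
        base = supervised_baseline(X_train, y_train, spec, cfg)
        sup_f2 = f2_score(base.predict(X_test), y_test)
        m_self, tr_self = self_train(
            X_train, y_train, X_u, spec, cfg, X_test, y_test, y_u_true=y_u
        )
        m_co, tr_co = co_train(
            X_train, y_train, X_u, spec, cfg, X_test, y_test, y_u_true=y_u
        )
        runs.append(
            BenchmarkRun(
                seed=seed,
                supervised_f2=sup_f2,
                self_f2=f2_score(m_self.predict(X_test), y_test),
                co_f2=f2_score(m_co.predict(X_test), y_test),
                self_trace=tr_self,
                co_trace=tr_co,
            )
        )
    return runs
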