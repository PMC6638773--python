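"""End-to-end pipeline: clean -> featurize -> train -> evaluate -> signal.

A RunConfig (flat YAML, one section per stage) drives the whole run; one
global seed fans out to per-stage seeds through a fixed derivation so each
stage is independently reproducible.  Every run writes a manifest recording
versions, seeds, input digests and the metric summary — enough to reproduce
any reported number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .corpus_io import BotRuleSet, RegionSpec, clean_corpus, filter_location, load_corpus, load_labels, save_corpus
from .evaluation import confusion, f_beta, prf_accuracy
from .features import build_vocabulary, featurize_corpus, tokenize
from .learners import LearnerSpec, fit
from .lexicons import load_lexicons
from .semisup import IterLabelConfig, co_train, self_train, supervised_baseline
from .signals import correlate, daily_signal, load_reference_series, moving_average, save_series

logger = logging.getLogger(__name__)

_STAGE_SEEDS = {"split": 11, "train": 23, "semisup": 37, "signal": 53}


def derive_seed(global_seed: int, stage: str) -> int:
    """Fixed per-stage seed derivation (stable across runs and platforms)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Parameters for every stage; unset paths skip their stage."""

    corpus: str | None = None
    labels: str | None = None
    unlabelled: str | None = None
    reference: str | None = None
    out_dir: str = "run_out"
    region: str | None = None  # "uk" or None
    drop_nogeo: bool = False
    ngram_min: int = 1
    ngram_max: int = 2
    min_doc_freq: int = 2
    family: str = "logistic_regression"
    hyperparams: dict = field(default_factory=dict)
    method: str = "supervised"  # supervised | selftrain | cotrain
    theta: float = 0.9
    batch_size: int = 200
    patience: int = 10
    balance_fraction: float | None = 0.47
    train_fraction: float = 0.7
    window: int = 7
    signal_mode: str = "proportion"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "symptweet_version": __version__,
        "config": cfg.to_dict(),
        "inputs": {},
        "stages": {},
    }
    if cfg.corpus is None:
        raise FileNotFoundError("RunConfig.corpus is required")
    for name in ("corpus", "labels", "unlabelled", "reference"):
        p = getattr(cfg, name)
        if p is not None:
            if not Path(p).exists():
                raise FileNotFoundError(f"input {name} not found: {p}")
            manifest["inputs"][name] = {"path": str(p), "sha256_16": _digest(p)}

    import numpy as np

    # ---- clean ---------------------------------------------------------
    tweets = load_corpus(cfg.corpus)
    if cfg.region == "uk":
        tweets = filter_location(tweets, RegionSpec.uk_default(keep_missing=not cfg.drop_nogeo))
    cleaned, report = clean_corpus(tweets, BotRuleSet())
    save_corpus(cleaned, out / "clean.jsonl")
    manifest["stages"]["clean"] = report.to_dict()

    # ---- featurize -----------------------------------------------------
    lex = load_lexicons()
    labels_map = load_labels(cfg.labels) if cfg.labels else {}
    labelled = [t for t in cleaned if t.id in labels_map or t.label]
    y_all = [labels_map.get(t.id, t.label) for t in labelled]
    if not labelled:
        raise ValueError("no labelled tweets available for training")

    rng = np.random.default_rng(derive_seed(cfg.seed, "split"))
    idx = rng.permutation(len(labelled))
    n_train = int(round(cfg.train_fraction * len(labelled)))
    tr_idx, te_idx = idx[:n_train], idx[n_train:]
    train_texts = [labelled[i].text for i in tr_idx]
    vocab = build_vocabulary(
        [tokenize(t, lex) for t in train_texts],
        n_range=(cfg.ngram_min, cfg.ngram_max),
        min_doc_freq=cfg.min_doc_freq,
    )
    X_train = featurize_corpus(train_texts, vocab, lex)
    y_train = [y_all[i] for i in tr_idx]
    X_test = featurize_corpus([labelled[i].text for i in te_idx], vocab, lex)
    y_test = [y_all[i] for i in te_idx]
    manifest["stages"]["featurize"] = {"vocabulary_size": len(vocab), "n_labelled": len(labelled)}

    # ---- train ---------------------------------------------------------
    spec = LearnerSpec(cfg.family, cfg.hyperparams, seed=derive_seed(cfg.seed, "train"))
    itcfg = IterLabelConfig(
        theta=cfg.theta, batch_size=cfg.batch_size, patience=cfg.patience,
        seed=derive_seed(cfg.seed, "semisup"), balance_fraction=cfg.balance_fraction,
    )
    if cfg.method == "supervised" or cfg.unlabelled is None:
        model = supervised_baseline(X_train, y_train, spec, itcfg)
        trace = None
    else:
        pool = load_corpus(cfg.unlabelled)
        X_u = featurize_corpus([t.text for t in pool], vocab, lex)
        runner = {"selftrain": self_train, "cotrain": co_train}[cfg.method]
        model, trace = runner(X_train, y_train, X_u, spec, itcfg, X_test, y_test)
        trace.to_dataframe().to_json(out / "trace.json", orient="records")

    # ---- evaluate ------------------------------------------------------
    pred = model.predict(X_test)
    cm = confusion(pred, y_test)
    p, r, acc = prf_accuracy(cm)
    metrics = {
        "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
        "precision": round(p, 3), "recall": round(r, 3),
        "accuracy_pct": round(100 * acc, 1),
        "f1": round(f_beta(p, r, 1.0), 3), "f2": round(f_beta(p, r, 2.0), 3),
    }
    manifest["stages"]["evaluate"] = metrics

    # ---- signal --------------------------------------------------------
    if cfg.reference is not None:
        all_X = featurize_corpus([t.text for t in cleaned], vocab, lex)
        stream_pred = model.predict(all_X)
        sig = daily_signal([t.timestamp for t in cleaned], list(stream_pred), mode=cfg.signal_mode)
        sig_s = moving_average(sig, cfg.window)
        ref = moving_average(load_reference_series(cfg.reference), cfg.window)
        res = correlate(sig_s, ref)
        save_series(sig_s, out / "signal.csv", value_name="signal")
        manifest["stages"]["signal"] = {"r": round(res.r, 3), "p": res.p, "n": res.n}

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
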