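"""Dual-loss training, shuffle control, and cross-validated experiments.

The loss is categorical cross-entropy on the decoded tokens plus
``lambda * MSE`` between the encoder's 13-unit head output and the reference
MFCC sequence; the published training settings (learning rate 5e-4, lambda
0.1, batch 16, 800 epochs, Adam) are the defaults.

Experiments follow the study scheme: stratified five-fold cross-validation
over the 80 trials (each fold holds 16 test segments, 2 per sentence), ten
independently seeded model trainings per fold, one decoded sentence per
(model, fold, test segment) -> up to 800 decode results per condition.
Cross-task transfer ("overt -> covert") trains on one speech condition and
tests on the other for the same trial split.  The shuffle control permutes
the time frames of every training segment to establish the chance floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .audiofeat import TrainingExample, pair_for_training
from .corpus import END_TOKEN, START_TOKEN
from .models import ModelConfig, Seq2SeqDecoder, build_model
from .nn import Adam, Tensor
from .preprocess import FeatureSequence, extract_features
from .synth import SyntheticDataset


@dataclass
class TrainConfig:
    learning_rate: float = 0.0005
    mfcc_penalty: float = 0.1  # lambda
    batch_size: int = 16
    epochs: int = 800
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mfcc_penalty < 0:
            raise ValueError("mfcc_penalty must be >= 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class ExperimentPlan:
    train_task: str  # "overt" or "covert"
    test_task: str
    architecture: str = "transformer"
    shuffle_control: bool = False
    folds: int = 5
    repeats_per_fold: int = 10

    def __post_init__(self) -> None:
        for t in (self.train_task, self.test_task):
            if t not in ("overt", "covert"):
                raise ValueError(f"task must be overt or covert, got {t!r}")


@dataclass
class DecodeResult:
    fold: int
    repeat: int
    trial: int
    task: str
    reference: tuple[int, ...]  # scored tokens only
    hypothesis: tuple[int, ...]


def loss(logits: Tensor, target_tokens: np.ndarray, mfcc_pred: Tensor,
         mfcc_target: np.ndarray, penalty: float) -> tuple[Tensor, float, float]:
    """CE + penalty * MSE; returns (total, ce_value, mse_value)."""
    target_tokens = np.asarray(target_tokens)
    mfcc_target = np.asarray(mfcc_target, dtype=np.float64)
    if not (np.isfinite(logits.data).all() and np.isfinite(mfcc_pred.data).all()
            and np.isfinite(mfcc_target).all()):
        raise ValueError("non-finite values in loss inputs")
    b, m, _ = logits.shape
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(b)[:, None], np.arange(m)[None, :], target_tokens]
    ce = -picked.mean()
    diff = mfcc_pred - Tensor(mfcc_target)
    mse = (diff * diff).mean()
    total = ce + penalty * mse
    return total, float(ce.data), float(mse.data)


def shuffle_features(features: FeatureSequence, seed: int) -> FeatureSequence:
    """Permute time frames (rows) with a seeded RNG; electrodes untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(features.n_frames)
    return replace(features, data=features.data[perm])


def _stack(examples: Sequence[TrainingExample]):
    x = np.stack([e.features.data for e in examples])
    mfcc = np.stack([e.mfcc.data for e in examples])
    toks = np.array([e.tokens for e in examples])
    return x, mfcc, toks[:, :-1], toks[:, 1:]  # teacher-forced in / shifted out


def train_model(examples: Sequence[TrainingExample], model_config: ModelConfig,
                config: TrainConfig, log: list[dict] | None = None) -> Seq2SeqDecoder:
    """Train one decoder on the given examples with the dual loss."""
    x_all, mfcc_all, tok_in, tok_out = _stack(examples)
    model = build_model(model_config, seed=config.seed)
    model.training = True
    opt = Adam(model.parameters(), lr=config.learning_rate)
    order_rng = np.random.default_rng(config.seed + 10_000)
    n = len(examples)
    for epoch in range(config.epochs):
        order = order_rng.permutation(n)
        ce_sum = mse_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            feats = Tensor(x_all[idx])
            logits, mfcc_pred = model.forward(feats, tok_in[idx])
            total, ce, mse = loss(logits, tok_out[idx], mfcc_pred, mfcc_all[idx],
                                  config.mfcc_penalty)
            opt.zero_grad()
            total.backward()
            opt.step()
            ce_sum += ce
            mse_sum += mse
            n_batches += 1
        if log is not None:
            log.append({"epoch": epoch, "ce": ce_sum / n_batches,
                        "mse": mse_sum / n_batches})
    model.training = False
    return model


def stratified_folds(dataset: SyntheticDataset, n_folds: int, seed: int) -> list[list[int]]:
    """Partition trials into folds, stratified by sentence so each fold holds
    an equal share of every sentence (80 trials / 5 folds -> 2 x 8 each)."""
    rng = np.random.default_rng(seed)
    by_sentence: dict[int, list[int]] = {}
    for trial, s in enumerate(dataset.schedule.sentence_indices):
        by_sentence.setdefault(s, []).append(trial)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for s in sorted(by_sentence):
        trials = np.array(by_sentence[s])
        rng.shuffle(trials)
        for i, trial in enumerate(trials):
            folds[i % n_folds].append(int(trial))
    if any(not f for f in folds):
        raise ValueError(
            f"{n_folds} folds leave some folds without test trials; "
            f"use fewer folds for {len(dataset.schedule.sentence_indices)} trials"
        )
    return [sorted(f) for f in folds]


TrainFn = Callable[[Sequence[TrainingExample], int], Seq2SeqDecoder]


def run_cv(plan: ExperimentPlan, dataset: SyntheticDataset, config: TrainConfig,
           model_config: ModelConfig | None = None,
           features_by_task: dict[str, list[FeatureSequence]] | None = None,
           train_fn: TrainFn | None = None) -> list[DecodeResult]:
    """Cross-validated train/decode for one experimental condition.

    ``features_by_task`` may carry precomputed features (keyed by task) to
    avoid refiltering; ``train_fn(examples, seed)`` may replace the default
    trainer (e.g. with a stub when only the bookkeeping is under test).
    """
    pairing = "overt_model" if plan.train_task == "overt" else "covert_model"
    needed = {plan.train_task, plan.test_task}
    if features_by_task is None:
        features_by_task = {t: extract_features(dataset, tasks=(t,)) for t in needed}
    train_examples = pair_for_training(pairing, dataset, features_by_task[plan.train_task])
    test_feats = {f.trial: f for f in features_by_task[plan.test_task]}
    if model_config is None:
        k = train_examples[0].features.n_electrodes
        model_config = ModelConfig(n_electrodes=k, architecture=plan.architecture)
    if train_fn is None:
        def train_fn(examples: Sequence[TrainingExample], seed: int) -> Seq2SeqDecoder:
            return train_model(examples, model_config, replace(config, seed=seed))

    folds = stratified_folds(dataset, plan.folds, config.seed)
    results: list[DecodeResult] = []
    for fold_idx, test_trials in enumerate(folds):
        test_set = set(test_trials)
        fold_train = [e for e in train_examples if e.trial not in test_set]
        if any(e.trial in test_set for e in fold_train):
            raise RuntimeError(f"fold {fold_idx}: train/test trial leakage")
        if plan.shuffle_control:
            fold_train = [
                replace(e, features=shuffle_features(e.features, config.seed + 31 * e.trial))
                for e in fold_train
            ]
        x_test = np.stack([test_feats[t].data for t in test_trials])
        refs = [dataset.sentences[test_feats[t].sentence_index].scored_tokens
                for t in test_trials]
        for repeat in range(plan.repeats_per_fold):
            seed = config.seed + 1000 * fold_idx + repeat
            model = train_fn(fold_train, seed)
            hyps = model.decode_greedy(x_test)
            for trial, ref, hyp in zip(test_trials, refs, hyps):
                results.append(
                    DecodeResult(fold=fold_idx, repeat=repeat, trial=trial,
                                 task=plan.test_task, reference=tuple(ref),
                                 hypothesis=tuple(int(t) for t in hyp))
                )
    return results
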