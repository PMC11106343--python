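"""Dual loss, shuffle control, fold bookkeeping, and cross-task transfer."""

import numpy as np
import pytest

from ecogseq import (
    ExperimentPlan,
    ModelConfig,
    SynthConfig,
    TrainConfig,
    extract_features,
    generate_dataset,
    make_schedule,
)
from ecogseq.evaluate import aggregate
from ecogseq.nn import Tensor
from ecogseq.train import (
    DecodeResult,
    loss,
    run_cv,
    shuffle_features,
    stratified_folds,
    train_model,
)


class StubModel:
    """Decodes a fixed sentence; stands in for a trained network when only
    the cross-validation bookkeeping is under test."""

    def __init__(self, tokens=(0, 2, 4)):
        self.tokens = list(tokens)

    def decode_greedy(self, features, max_len=5):
        n = features.shape[0] if features.ndim == 3 else 1
        return [list(self.tokens) for _ in range(n)]


# -- loss --------------------------------------------------------------------

def test_loss_matches_hand_computed_toy_case():
    """Two positions, two live classes: CE and MSE worked out by hand."""
    logits = Tensor(np.array([[[np.log(3.0), 0, -50, -50, -50, -50, -50, -50],
                               [0, np.log(1.0), -50, -50, -50, -50, -50, -50]]]))
    targets = np.array([[0, 1]])
    # p(class0 | pos0) = 3/4, p(class1 | pos1) = 1/2
    expected_ce = -(np.log(0.75) + np.log(0.5)) / 2
    mfcc_pred = Tensor(np.array([[[1.0, 2.0]]]))
    mfcc_target = np.array([[[0.0, 0.0]]])
    expected_mse = (1.0 + 4.0) / 2
    total, ce, mse = loss(logits, targets, mfcc_pred, mfcc_target, penalty=0.1)
    assert ce == pytest.approx(expected_ce, rel=1e-5)
    assert mse == pytest.approx(expected_mse, rel=1e-5)
    assert float(total.data) == pytest.approx(expected_ce + 0.1 * expected_mse, rel=1e-5)


def test_loss_reduces_to_cross_entropy_when_penalty_zero():
    rng = np.random.default_rng(0)
    logits = Tensor(rng.normal(size=(2, 4, 8)))
    targets = rng.integers(0, 8, size=(2, 4))
    mfcc_pred = Tensor(rng.normal(size=(2, 6, 13)))
    total, ce, mse = loss(logits, targets, mfcc_pred, rng.normal(size=(2, 6, 13)), 0.0)
    assert float(total.data) == pytest.approx(ce)
    assert mse > 0


def test_loss_is_near_zero_for_perfect_predictions():
    logits = np.full((1, 3, 8), -100.0)
    targets = np.array([[0, 2, 4]])
    for i, t in enumerate(targets[0]):
        logits[0, i, t] = 100.0
    mfcc = np.ones((1, 5, 13))
    total, ce, mse = loss(Tensor(logits), targets, Tensor(mfcc), mfcc, 0.1)
    assert float(total.data) == pytest.approx(0.0, abs=1e-6)


def test_loss_rejects_non_finite_inputs():
    bad = np.full((1, 2, 8), np.nan)
    with pytest.raises(ValueError, match="non-finite"):
        loss(Tensor(bad), np.zeros((1, 2), int), Tensor(np.zeros((1, 2, 13))),
             np.zeros((1, 2, 13)), 0.1)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(mfcc_penalty=-0.1)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
    with pytest.raises(ValueError):
        ExperimentPlan("overt", "listening")


# -- shuffle control ---------------------------------------------------------

def test_shuffle_preserves_marginals_and_is_seeded(small_features):
    feat = small_features["covert"][0]
    shuf = shuffle_features(feat, seed=7)
    assert shuf.data.shape == feat.data.shape
    np.testing.assert_array_equal(np.sort(shuf.data, axis=0), np.sort(feat.data, axis=0))
    np.testing.assert_array_equal(shuffle_features(feat, seed=7).data, shuf.data)
    assert not np.array_equal(shuf.data, feat.data)


def test_shuffle_destroys_temporal_autocorrelation():
    from dataclasses import replace

    t = np.linspace(0, 4 * np.pi, 700)
    smooth = np.sin(t)[:, None] * np.ones((1, 4))
    feat = shuffle_features(
        replace_feature(smooth), seed=3
    )
    def lag1(x):
        return np.corrcoef(x[:-1, 0], x[1:, 0])[0, 1]
    assert lag1(smooth) > 0.99
    assert abs(lag1(feat.data)) < 0.2


def replace_feature(data):
    from ecogseq.preprocess import FeatureSequence

    return FeatureSequence(data=data, fs=200.0, trial=0, task="covert", sentence_index=0)


# -- folds and cross-validation ----------------------------------------------

def test_stratified_folds_partition_and_balance():
    ds = generate_dataset(SynthConfig(seed=51), make_schedule(80, seed=52))
    folds = stratified_folds(ds, 5, seed=0)
    flat = [t for f in folds for t in f]
    assert sorted(flat) == list(range(80))
    for fold in folds:
        sents = [ds.schedule.sentence_indices[t] for t in fold]
        assert np.bincount(sents, minlength=8).tolist() == [2] * 8


def make_stub_scale_study(n_trials=80, seed=71):
    """80-trial dataset + fabricated features for bookkeeping-only tests:
    no bursts and no filtering, so only the orchestration is exercised."""
    from ecogseq.preprocess import FeatureSequence

    cfg = SynthConfig(n_electrodes=2, snr_db=-np.inf,
                      informative_sets={t: (0,) for t in range(6)}, seed=seed)
    ds = generate_dataset(cfg, make_schedule(n_trials, seed=seed + 1))
    rng = np.random.default_rng(seed + 2)
    feats = {
        task: [
            FeatureSequence(data=rng.normal(size=(120, 2)), fs=200.0, trial=r.trial,
                            task=task, sentence_index=r.sentence_index)
            for r in ds.recordings if r.task == task
        ]
        for task in ("overt", "covert")
    }
    return ds, feats


def test_cv_bookkeeping_produces_800_results():
    """5 folds x 10 repeats x 16 test segments = 800 results; 64/16 split."""
    ds, feats = make_stub_scale_study()
    sizes = []

    def stub_train(examples, seed):
        sizes.append(len(examples))
        return StubModel()

    plan = ExperimentPlan("covert", "covert", folds=5, repeats_per_fold=10)
    results = run_cv(plan, ds, TrainConfig(seed=1),
                     features_by_task=feats, train_fn=stub_train)
    assert len(results) == 800
    assert all(s == 64 for s in sizes)
    tested = {(r.fold, r.trial) for r in results}
    assert len(tested) == 80  # every trial tested in exactly one fold
    assert all(len(r.reference) == 3 for r in results)


def test_too_many_folds_for_the_schedule_is_an_error(small_dataset):
    with pytest.raises(ValueError, match="folds"):
        stratified_folds(small_dataset, 5, seed=0)


def test_cv_smoke_run_with_two_folds(small_dataset, small_features):
    plan = ExperimentPlan("overt", "covert", folds=2, repeats_per_fold=1)
    results = run_cv(plan, small_dataset, TrainConfig(seed=2),
                     features_by_task=small_features,
                     train_fn=lambda ex, seed: StubModel((1, 3, 5)))
    agg = aggregate(results)
    assert agg["n_results"] == small_dataset.n_trials
    assert set(agg["per_fold"]) == {0, 1}
    assert all(r.task == "covert" for r in results)


def test_transfer_improves_with_electrode_overlap():
    """Overt-trained decoding of covert speech: shared overt/covert electrode
    codes (alpha=1) must beat disjoint codes (alpha=0).  Scaled-down run."""
    ters = {}
    for alpha in (0.0, 1.0):
        ds = generate_dataset(
            SynthConfig(seed=61, overlap=alpha), make_schedule(32, seed=62))
        feats = {t: extract_features(ds, tasks=(t,)) for t in ("overt", "covert")}
        plan = ExperimentPlan("overt", "covert", folds=2, repeats_per_fold=1)
        res = run_cv(plan, ds, TrainConfig(epochs=150, seed=63), features_by_task=feats)
        ters[alpha] = aggregate(res)["mean_ter"]
    assert ters[1.0] < ters[0.0] - 10.0
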