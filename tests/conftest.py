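"""Shared fixtures.

``small_dataset`` is a cheap 16-trial synthetic dataset for unit tests.
``recovery`` is the session-scoped scaled-down decoding study (80 trials,
32 electrodes, 2 folds x 1 repeat, 100 epochs) shared by the synthetic-
recovery and saliency-recovery acceptance tests so the training cost is paid
once.
"""

from __future__ import annotations

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
from ecogseq.audiofeat import pair_for_training
from ecogseq.saliency import contributions_for_segments
from ecogseq.train import run_cv, stratified_folds, train_model


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SynthConfig(seed=11), make_schedule(16, seed=12))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return {
        task: extract_features(small_dataset, tasks=(task,))
        for task in ("overt", "covert")
    }


@pytest.fixture(scope="session")
def recovery():
    """Scaled-down decoding study on the standard synthetic conditions:
    high SNR, full covert/overt electrode overlap, covert attenuation 0.7."""
    dataset = generate_dataset(SynthConfig(seed=1), make_schedule(80, seed=2))
    feats = {t: extract_features(dataset, tasks=(t,)) for t in ("overt", "covert")}
    config = TrainConfig(epochs=100, seed=5)
    scaled = dict(folds=2, repeats_per_fold=1)
    results = {
        "covert_covert": run_cv(
            ExperimentPlan("covert", "covert", **scaled), dataset, config,
            features_by_task=feats),
        "overt_covert": run_cv(
            ExperimentPlan("overt", "covert", **scaled), dataset, config,
            features_by_task=feats),
        "shuffle": run_cv(
            ExperimentPlan("covert", "covert", shuffle_control=True, **scaled),
            dataset, config, features_by_task=feats),
    }
    # one overt model + held-out maps for the electrode-contribution check
    examples = pair_for_training("overt_model", dataset, feats["overt"])
    test_trials = set(stratified_folds(dataset, 2, config.seed)[0])
    model = train_model(
        [e for e in examples if e.trial not in test_trials],
        ModelConfig(dataset.config.n_electrodes), config)
    test_feats = [f for f in feats["overt"] if f.trial in test_trials]
    refs = [dataset.sentences[f.sentence_index].scored_tokens for f in test_feats]
    contrib = contributions_for_segments(model, test_feats, refs)
    return {
        "dataset": dataset,
        "features": feats,
        "results": results,
        "contributions": contrib,
    }
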