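"""Synthetic generator: planted-code calibration, determinism, audio oracle."""

import numpy as np
import pytest
from scipy import signal

from ecogseq.audiofeat import compute_mfcc
from ecogseq.corpus import build_sentences, make_schedule
from ecogseq.io import read_container, write_container
from ecogseq.synth import (
    HIGH_GAMMA_BAND,
    SynthConfig,
    covert_electrode_sets,
    generate_audio,
    generate_dataset,
    overt_electrode_sets,
)


def band_power_in_window(sig: np.ndarray, fs: float, window: slice) -> float:
    f, pxx = signal.welch(sig[window], fs=fs, nperseg=min(1024, window.stop - window.start))
    band = (f >= HIGH_GAMMA_BAND[0]) & (f <= HIGH_GAMMA_BAND[1])
    return float(np.trapezoid(pxx[band], f[band]))


def token_window(rec, slot: int) -> slice:
    a = int(rec.sentence_interval[0] * rec.fs)
    b = int(rec.sentence_interval[1] * rec.fs)
    third = (b - a) // 3
    return slice(a + slot * third, a + (slot + 1) * third)


def test_dataset_is_bitwise_deterministic_given_seed():
    cfg = SynthConfig(seed=21)
    sched = make_schedule(8, seed=22)
    a = generate_dataset(cfg, sched)
    b = generate_dataset(cfg, sched)
    for ra, rb in zip(a.recordings, b.recordings):
        np.testing.assert_array_equal(ra.signal, rb.signal)
        if ra.audio is not None:
            np.testing.assert_array_equal(ra.audio, rb.audio)


def test_audio_only_for_overt_and_perception(small_dataset):
    for rec in small_dataset.recordings:
        assert (rec.audio is not None) == (rec.task in ("overt", "perception"))
        t0, t1 = rec.sentence_interval
        assert t1 - t0 == pytest.approx(small_dataset.config.segment_duration)


def test_planted_burst_snr_matches_config(small_dataset):
    """Welch band power on a token's electrodes inside its window exceeds
    background electrodes by the configured SNR within about 1 dB."""
    ds = small_dataset
    cfg = ds.config
    background = [e for e in range(cfg.n_electrodes)
                  if all(e not in s for s in ds.overt_sets.values())
                  and all(abs(e - i) > 1 for s in ds.overt_sets.values() for i in s)]
    ratios = []
    for rec in [r for r in ds.recordings if r.task == "overt"]:
        sent = ds.sentences[rec.sentence_index]
        for slot, token in enumerate(sent.scored_tokens):
            win = token_window(rec, slot)
            p_inf = np.mean([band_power_in_window(rec.signal[e], rec.fs, win)
                             for e in ds.overt_sets[token]])
            p_bg = np.mean([band_power_in_window(rec.signal[e], rec.fs, win)
                            for e in background[:4]])
            ratios.append((p_inf - p_bg) / p_bg)  # burst power over background
    snr_db = 10 * np.log10(np.mean(ratios))
    assert snr_db == pytest.approx(cfg.snr_db, abs=1.0)


def test_bursts_off_leaves_no_token_information():
    cfg = SynthConfig(seed=31, snr_db=-np.inf)
    ds = generate_dataset(cfg, make_schedule(8, seed=32))
    rec = ds.recordings[0]
    sent = ds.sentences[rec.sentence_index]
    win = token_window(rec, 0)
    p_inf = np.mean([band_power_in_window(rec.signal[e], rec.fs, win)
                     for e in ds.overt_sets[sent.scored_tokens[0]]])
    p_bg = np.mean([band_power_in_window(rec.signal[e], rec.fs, win)
                    for e in range(28, 32)])
    assert abs(10 * np.log10(p_inf / p_bg)) < 2.0


def test_full_overlap_and_unit_gain_reproduce_the_overt_law():
    cfg = SynthConfig(overlap=1.0, covert_gain=1.0, covert_spread=0.0, seed=41)
    assert covert_electrode_sets(cfg) == overt_electrode_sets(cfg)
    ds = generate_dataset(cfg, make_schedule(8, seed=42))
    # same electrodes, same planted power: overt and covert in-window band
    # powers agree on informative electrodes up to noise realization
    powers = {"overt": [], "covert": []}
    for rec in ds.recordings:
        if rec.task == "perception":
            continue
        sent = ds.sentences[rec.sentence_index]
        for slot, token in enumerate(sent.scored_tokens):
            win = token_window(rec, slot)
            powers[rec.task].append(np.mean(
                [band_power_in_window(rec.signal[e], rec.fs, win)
                 for e in ds.overt_sets[token]]))
    ratio = np.mean(powers["covert"]) / np.mean(powers["overt"])
    assert 10 * abs(np.log10(ratio)) < 1.0


def test_covert_sets_interpolate_with_overlap():
    lo = covert_electrode_sets(SynthConfig(overlap=0.0))
    hi = covert_electrode_sets(SynthConfig(overlap=1.0))
    overt = overt_electrode_sets(SynthConfig())
    for t in range(6):
        assert not set(lo[t]) & set(overt[t])
        assert set(hi[t]) == set(overt[t])


def test_config_validation():
    with pytest.raises(ValueError, match="overlap"):
        SynthConfig(overlap=1.5)
    with pytest.raises(ValueError, match="covert_gain"):
        SynthConfig(covert_gain=0.0)
    with pytest.raises(ValueError, match="non-empty"):
        SynthConfig(informative_sets={0: ()})
    with pytest.raises(ValueError, match="electrode range"):
        SynthConfig(informative_sets={0: (99,)})


def test_audio_mfcc_separates_sentences_beyond_noise():
    """Inter-sentence MFCC distance exceeds intra-sentence (re-seeded noise)
    distance for every sentence pair: the acoustic tokens are discriminable."""
    sentences = build_sentences()
    reps = {}
    for i, s in enumerate(sentences):
        reps[i] = [
            compute_mfcc(generate_audio(s, 16000, rng=np.random.default_rng(seed)), 16000).data.mean(axis=0)
            for seed in (0, 1)
        ]
    intra = max(np.linalg.norm(reps[i][0] - reps[i][1]) for i in reps)
    inter = min(
        np.linalg.norm(reps[i][0] - reps[j][0])
        for i in reps for j in reps if i < j
    )
    assert inter > intra


def test_audio_rejects_low_sample_rate():
    with pytest.raises(ValueError, match="8000"):
        generate_audio(build_sentences()[0], 4000)


def test_container_round_trip(tmp_path, small_dataset):
    path = tmp_path / "ds.h5"
    write_container(small_dataset, path)
    back = read_container(path)
    assert back.schedule == small_dataset.schedule
    assert back.overt_sets == small_dataset.overt_sets
    assert back.covert_sets == small_dataset.covert_sets
    orig = small_dataset.get(3, "covert")
    restored = back.get(3, "covert")
    np.testing.assert_array_equal(orig.signal, restored.signal)
    assert restored.sentence_interval == pytest.approx(orig.sentence_interval)
    np.testing.assert_array_equal(
        small_dataset.get(3, "overt").audio, back.get(3, "overt").audio
    )
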