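"""Feature pipeline: trimming, filtering, envelope extraction, z-scoring."""

import numpy as np
import pytest
from scipy import signal

from ecogseq.preprocess import (
    FIR_TAPS,
    FS_FEATURES,
    FS_INTERMEDIATE,
    HIGH_GAMMA_BANDS,
    EcogSegment,
    bandpass_bank,
    highgamma_envelope,
    highgamma_features,
    resample_and_notch,
    trim_segments,
)


def make_segment(sig: np.ndarray, fs: float) -> EcogSegment:
    return EcogSegment(signal=sig, fs=fs, trial=0, task="overt", sentence_index=0)


# -- trimming ---------------------------------------------------------------

def test_trim_yields_one_segment_per_trial_and_task(small_dataset):
    segs = trim_segments(small_dataset)
    assert len(segs) == small_dataset.n_trials * 3
    lengths = {s.signal.shape[1] for s in segs}
    assert lengths == {int(3.5 * 1200)}  # max sentence duration at 1200 Hz


def test_trim_excludes_dummy_period(small_dataset):
    seg = trim_segments(small_dataset, tasks=("overt",))[0]
    rec = small_dataset.get(seg.trial, "overt")
    start = int(round(rec.sentence_interval[0] * rec.fs))
    np.testing.assert_array_equal(seg.signal, rec.signal[:, start : start + seg.signal.shape[1]])


def test_trim_reports_bad_interval_with_trial_id(small_dataset):
    import copy

    broken = copy.deepcopy(small_dataset)
    rec = broken.get(5, "covert")
    rec.sentence_interval = (2.0, 1.0)
    with pytest.raises(ValueError, match="trial 5"):
        trim_segments(broken)


def test_trim_can_exclude_electrodes(small_dataset):
    segs = trim_segments(small_dataset, tasks=("overt",), exclude_electrodes=(0, 31))
    assert segs[0].signal.shape[0] == 30


def test_trim_before_filtering_order_is_material(small_dataset):
    """Filtering the whole recording first, then cutting, leaks pre-segment
    transients into the segment: the mandated trim-first order must differ."""
    rec = small_dataset.get(0, "overt")
    seg = trim_segments(small_dataset, tasks=("overt",))[0]
    trim_first = resample_and_notch(seg).signal
    whole = resample_and_notch(make_segment(rec.signal, rec.fs))
    a400 = int(round(rec.sentence_interval[0] * FS_INTERMEDIATE))
    filter_first = whole.signal[:, a400 : a400 + trim_first.shape[1]]
    assert not np.allclose(trim_first, filter_first, atol=1e-3)


# -- resampling and notches -------------------------------------------------

@pytest.mark.parametrize("fs", [1200.0, 9600.0])
def test_resample_produces_400_hz_within_one_sample(fs):
    n = int(3.5 * fs)
    seg = make_segment(np.random.default_rng(0).normal(size=(2, n)), fs)
    out = resample_and_notch(seg)
    assert out.fs == FS_INTERMEDIATE
    assert abs(out.signal.shape[1] - 1400) <= 1


def test_resample_rejects_low_rate():
    with pytest.raises(ValueError):
        resample_and_notch(make_segment(np.zeros((1, 100)), 200.0))


@pytest.mark.parametrize("f0", [50.0, 100.0])
def test_notch_attenuates_line_frequency_by_20_db(f0):
    t = np.arange(int(4 * 1200)) / 1200
    seg = make_segment(np.sin(2 * np.pi * f0 * t)[None], 1200.0)
    out = resample_and_notch(seg).signal[0][200:-200]  # drop filter edges
    atten_db = 20 * np.log10(np.std(np.sin(2 * np.pi * f0 * t)) / np.std(out))
    assert atten_db >= 20.0


def test_dc_passes_through_unchanged():
    seg = make_segment(np.full((1, 4800), 3.0), 1200.0)
    out = resample_and_notch(seg).signal[0]
    np.testing.assert_allclose(out[200:-200], 3.0, atol=1e-2)


# -- filter bank and envelopes ----------------------------------------------

def test_filter_bank_minus6db_edges_sit_on_printed_passbands():
    for taps, (lo, hi) in zip(bandpass_bank(), HIGH_GAMMA_BANDS):
        w, h = signal.freqz(taps, worN=8192, fs=FS_INTERMEDIATE)
        mag = np.abs(h)
        for edge in (lo, hi):
            idx = np.argmin(np.abs(w - edge))
            edge_db = 20 * np.log10(mag[idx])
            assert edge_db == pytest.approx(-6.0, abs=1.5), f"band {lo}-{hi}, edge {edge}"
        center = (lo + hi) / 2
        assert mag[np.argmin(np.abs(w - center))] == pytest.approx(1.0, abs=0.05)


def test_filter_bank_covers_high_gamma_range():
    """The passband intervals tile 70-150 Hz: mostly overlapping, with a
    single 1 Hz seam (136-137 Hz, as printed) where the realized response
    still stays above -15 dB."""
    edges = sorted(HIGH_GAMMA_BANDS)
    assert edges[0][0] <= 70.0 and edges[-1][1] >= 150.0
    for (_, hi), (lo, _) in zip(edges[:-1], edges[1:]):
        assert lo - hi <= 1.0
    grid = np.linspace(70.0, 150.0, 801)
    best = np.full_like(grid, -np.inf)
    for taps in bandpass_bank():
        w, h = signal.freqz(taps, worN=grid, fs=FS_INTERMEDIATE)
        best = np.maximum(best, 20 * np.log10(np.abs(h) + 1e-12))
    assert best.min() >= -15.0


def test_am_tone_envelope_recovered_with_high_correlation():
    """100 Hz carrier, 2 Hz amplitude modulation: the band-averaged Hilbert
    envelope tracks the true modulator (r >= 0.9)."""
    fs = FS_INTERMEDIATE
    t = np.arange(int(5 * fs)) / fs
    modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t)
    x = (modulator * np.sin(2 * np.pi * 100.0 * t))[None]
    env = highgamma_envelope(x, fs)[0]
    r = np.corrcoef(env, modulator)[0, 1]
    assert r >= 0.9


def test_out_of_band_tone_is_suppressed():
    fs = FS_INTERMEDIATE
    t = np.arange(int(5 * fs)) / fs
    env30 = highgamma_envelope(np.sin(2 * np.pi * 30.0 * t)[None], fs)[0]
    env100 = highgamma_envelope(np.sin(2 * np.pi * 100.0 * t)[None], fs)[0]
    assert np.mean(env30**2) <= 0.01 * np.mean(env100**2)


def test_features_are_zscored_at_200_hz(small_dataset):
    seg = resample_and_notch(trim_segments(small_dataset, tasks=("covert",))[0])
    feat = highgamma_features(seg)
    assert feat.fs == FS_FEATURES
    assert feat.data.shape == (700, small_dataset.config.n_electrodes)
    np.testing.assert_allclose(feat.data.mean(axis=0), 0.0, atol=1e-6)
    np.testing.assert_allclose(feat.data.std(axis=0), 1.0, atol=1e-6)


def test_constant_channel_is_reported_by_electrode():
    sig = np.random.default_rng(0).normal(size=(3, 1400))
    sig[1] = 0.0
    with pytest.raises(ValueError, match=r"\[1\]"):
        highgamma_features(make_segment(sig, FS_INTERMEDIATE))


def test_features_require_400_hz_input():
    with pytest.raises(ValueError, match="400"):
        highgamma_features(make_segment(np.zeros((1, 1200)), 1200.0))
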