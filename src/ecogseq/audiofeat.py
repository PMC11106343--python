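"""MFCC training targets and their alignment to the encoder time axis.

MFCCs are computed with a 20 ms window and 5 ms step: pre-emphasis, Hamming
window, power spectrum, 26-filter mel bank, log, DCT-II (orthonormal), first
13 coefficients including c0, sinusoidal liftering.  They serve only as the
auxiliary regression target of the encoder ("feed-forward 1"); they are never
used at decode time, so strict audio/ECoG synchrony is not required.

For the *overt model* the MFCC source is the same trial's overt-task audio;
for the *covert model* no audio exists during covert speech, so the MFCC
source is the same trial's perception-task audio (same sentence content).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

from .corpus import START_TOKEN
from .preprocess import FeatureSequence
from .synth import SyntheticDataset

N_MFCC = 13  # fixed by the 13-unit encoder head


@dataclass
class MfccSequence:
    data: np.ndarray  # (n_frames, 13)
    frame_step: float  # s

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class AlignedMfcc:
    data: np.ndarray  # (target_len, 13)
    n_padded: int  # rows filled by edge-padding when audio was short


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, fs: float) -> np.ndarray:
    """Triangular mel filters on the rfft bins, shape (n_filters, nfft//2+1)."""
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(fs / 2.0), n_filters + 2))
    bins = np.floor((nfft + 1) * edges / fs).astype(int)
    bank = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        for b in range(lo, mid):
            bank[i, b] = (b - lo) / max(mid - lo, 1)
        for b in range(mid, hi):
            bank[i, b] = (hi - b) / max(hi - mid, 1)
    return bank


def compute_mfcc(audio: np.ndarray, fs: float, window_length: float = 0.020,
                 window_step: float = 0.005, n_filters: int = 26,
                 preemph: float = 0.97, lifter: int = 22) -> MfccSequence:
    """Standard 13-coefficient MFCCs (c0 included) of a mono waveform."""
    if fs < 8000:
        raise ValueError(f"fs must be >= 8000 Hz, got {fs}")
    audio = np.asarray(audio, dtype=np.float64)
    if audio.size == 0 or np.allclose(audio, 0.0):
        raise ValueError("audio is empty or all-zero")
    x = np.append(audio[0], audio[1:] - preemph * audio[:-1])
    win = int(round(window_length * fs))
    step = int(round(window_step * fs))
    n_frames = 1 + max(0, (x.size - win)) // step
    nfft = 1 << (win - 1).bit_length()
    idx = np.arange(win)[None, :] + step * np.arange(n_frames)[:, None]
    frames = x[np.minimum(idx, x.size - 1)] * np.hamming(win)
    power = np.abs(rfft(frames, n=nfft, axis=-1)) ** 2 / nfft
    feat = power @ mel_filterbank(n_filters, nfft, fs).T
    feat = np.log(np.maximum(feat, 1e-30))
    ceps = dct(feat, type=2, axis=-1, norm="ortho")[:, :N_MFCC]
    if lifter > 0:
        n = np.arange(N_MFCC)
        ceps = ceps * (1.0 + (lifter / 2.0) * np.sin(np.pi * n / lifter))
    if not np.isfinite(ceps).all():
        raise ValueError("MFCC produced non-finite frames")
    return MfccSequence(data=ceps, frame_step=window_step)


def align_to_encoder(mfcc: MfccSequence, stride: int, target_len: int) -> AlignedMfcc:
    """Decimate MFCC frames by the conv stride W and fit to the encoder length.

    Takes every ``stride``-th frame starting at frame 0, then edge-pads or
    truncates to exactly ``target_len`` rows.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if target_len <= 0:
        raise ValueError(f"target_len must be positive, got {target_len}")
    rows = mfcc.data[::stride]
    n_padded = 0
    if rows.shape[0] < target_len:
        n_padded = target_len - rows.shape[0]
        rows = np.vstack([rows, np.repeat(rows[-1:], n_padded, axis=0)])
    elif rows.shape[0] > target_len:
        rows = rows[:target_len]
    return AlignedMfcc(data=rows, n_padded=n_padded)


@dataclass
class TrainingExample:
    features: FeatureSequence  # ECoG features (L, K)
    mfcc: AlignedMfcc  # encoder-aligned target (N, 13)
    tokens: tuple[int, ...]  # [6, t1, t2, t3, 7]
    trial: int
    ecog_task: str
    audio_task: str


#: (ECoG task, audio task) per model variant
PAIRINGS = {"overt_model": ("overt", "overt"), "covert_model": ("covert", "perception")}


def pair_for_training(pairing: str, dataset: SyntheticDataset,
                      features: list[FeatureSequence], stride: int = 12,
                      audio_source: SyntheticDataset | None = None) -> list[TrainingExample]:
    """Assemble (ECoG features, aligned MFCC, token sequence) triples.

    ``features`` must contain the feature sequences of the pairing's ECoG
    task.  ``audio_source`` optionally substitutes another surrogate's
    dataset as the audio provider (same trial indices), the explicit analogue
    of borrowing a different participant's recordings when audio is unusable.
    """
    if pairing not in PAIRINGS:
        raise ValueError(f"pairing must be one of {sorted(PAIRINGS)}, got {pairing!r}")
    ecog_task, audio_task = PAIRINGS[pairing]
    audio_ds = audio_source or dataset
    feats = [f for f in features if f.task == ecog_task]
    if not feats:
        raise ValueError(f"no {ecog_task!r} feature sequences supplied")
    examples = []
    for feat in feats:
        try:
            rec = audio_ds.get(feat.trial, audio_task)
        except KeyError as e:
            raise ValueError(f"missing {audio_task!r} recording: {e.args[0]}") from None
        if rec.audio is None:
            raise ValueError(f"trial {feat.trial}: no audio for task {audio_task!r}")
        mfcc = compute_mfcc(rec.audio, rec.fs_audio)
        n = -(-feat.n_frames // stride)  # ceil(L / W), the encoder length
        aligned = align_to_encoder(mfcc, stride, n)
        tokens = dataset.sentences[feat.sentence_index].token_sequence
        examples.append(
            TrainingExample(features=feat, mfcc=aligned, tokens=tokens,
                            trial=feat.trial, ecog_task=ecog_task, audio_task=audio_task)
        )
    return examples
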