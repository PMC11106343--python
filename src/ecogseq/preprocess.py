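"""Raw recordings -> 200 Hz z-scored high-gamma features.

The mandated stage order is trim -> resample/notch -> band envelopes ->
z-score.  Trimming before any filtering keeps time-correlated filter
transients from one period leaking into another; every segment is cut to the
same length (the maximum sentence duration in the dataset) so a decoder
cannot read the sentence identity off the segment length.

Envelope extraction uses an 8-band FIR filter bank spanning 70-150 Hz
(passbands 68-78, 74-84, 82-92, 91-102, 101-112, 112-124, 124-136,
137-150 Hz).  Each band-passed signal's analytic amplitude (Hilbert envelope)
is computed, the eight envelopes are averaged, downsampled to 200 Hz, and
z-scored per electrode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
from scipy import signal

from .synth import SyntheticDataset

#: printed passbands of the eight FIR band-pass filters, Hz
HIGH_GAMMA_BANDS = (
    (68.0, 78.0), (74.0, 84.0), (82.0, 92.0), (91.0, 102.0),
    (101.0, 112.0), (112.0, 124.0), (124.0, 136.0), (137.0, 150.0),
)
FS_INTERMEDIATE = 400.0
FS_FEATURES = 200.0
FIR_TAPS = 401  # Hamming windowed-sinc; -6 dB points sit on the passband edges
NOTCH_FREQS = (50.0, 100.0)
NOTCH_Q = 30.0


@dataclass
class EcogSegment:
    signal: np.ndarray  # (n_electrodes, n_samples)
    fs: float
    trial: int
    task: str
    sentence_index: int


@dataclass
class FeatureSequence:
    """Time x electrode matrix of z-scored high-gamma envelopes at 200 Hz."""

    data: np.ndarray  # (L, K) float
    fs: float
    trial: int
    task: str
    sentence_index: int
    mean: np.ndarray | None = None  # per-electrode stats used for z-scoring
    sd: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]


def trim_segments(dataset: SyntheticDataset, tasks: tuple[str, ...] | None = None,
                  exclude_electrodes: tuple[int, ...] = ()) -> list[EcogSegment]:
    """Cut each recording to its sentence interval, dropping the dummy-word
    lead-in; every segment gets the dataset-wide maximum sentence duration.
    """
    recs = [r for r in dataset.recordings if tasks is None or r.task in tasks]
    if not recs:
        raise ValueError("no recordings for the requested tasks")
    max_dur = 0.0
    for rec in recs:
        t0, t1 = rec.sentence_interval
        if t1 <= t0:
            raise ValueError(f"trial {rec.trial} ({rec.task}): negative sentence interval")
        max_dur = max(max_dur, t1 - t0)
    segments = []
    keep = None
    for rec in recs:
        if exclude_electrodes:
            keep = [i for i in range(rec.signal.shape[0]) if i not in exclude_electrodes]
        n = int(round(max_dur * rec.fs))
        a = int(round(rec.sentence_interval[0] * rec.fs))
        if a + n > rec.signal.shape[1]:
            raise ValueError(
                f"trial {rec.trial} ({rec.task}): sentence interval exceeds recording"
            )
        sig = rec.signal[:, a : a + n]
        if keep is not None:
            sig = sig[keep]
        segments.append(
            EcogSegment(signal=sig.copy(), fs=rec.fs, trial=rec.trial,
                        task=rec.task, sentence_index=rec.sentence_index)
        )
    return segments


def resample_and_notch(segment: EcogSegment) -> EcogSegment:
    """Anti-aliased downsampling to 400 Hz, then 50/100 Hz IIR notches
    (Q=30, zero-phase)."""
    if segment.fs < FS_INTERMEDIATE:
        raise ValueError(f"fs {segment.fs} < {FS_INTERMEDIATE} Hz")
    frac = Fraction(int(round(FS_INTERMEDIATE)), int(round(segment.fs))).limit_denominator()
    x = signal.resample_poly(segment.signal, frac.numerator, frac.denominator, axis=-1)
    for f0 in NOTCH_FREQS:
        b, a = signal.iirnotch(f0, NOTCH_Q, fs=FS_INTERMEDIATE)
        x = signal.filtfilt(b, a, x, axis=-1)
    return EcogSegment(signal=x, fs=FS_INTERMEDIATE, trial=segment.trial,
                       task=segment.task, sentence_index=segment.sentence_index)


@lru_cache(maxsize=1)
def bandpass_bank(fs: float = FS_INTERMEDIATE, numtaps: int = FIR_TAPS) -> tuple[np.ndarray, ...]:
    """The eight FIR band-pass filters (Hamming windowed-sinc taps)."""
    return tuple(
        signal.firwin(numtaps, band, pass_zero="bandpass", fs=fs, window="hamming")
        for band in HIGH_GAMMA_BANDS
    )


def highgamma_envelope(x: np.ndarray, fs: float = FS_INTERMEDIATE) -> np.ndarray:
    """Band-averaged Hilbert envelope at the input rate (pre-decimation)."""
    env = np.zeros_like(x)
    for taps in bandpass_bank(fs):
        banded = signal.filtfilt(taps, [1.0], x, axis=-1)
        env += np.abs(signal.hilbert(banded, axis=-1))
    return env / len(HIGH_GAMMA_BANDS)


def highgamma_features(segment: EcogSegment) -> FeatureSequence:
    """400 Hz segment -> z-scored 200 Hz high-gamma FeatureSequence."""
    if segment.fs != FS_INTERMEDIATE:
        raise ValueError(f"expected {FS_INTERMEDIATE} Hz input, got {segment.fs}")
    env = highgamma_envelope(segment.signal, segment.fs)
    env = signal.resample_poly(env, 1, int(FS_INTERMEDIATE / FS_FEATURES), axis=-1)
    sd = env.std(axis=-1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"constant channel: electrode(s) {zero.tolist()} have zero variance")
    mean = env.mean(axis=-1)
    z = (env - mean[:, None]) / sd[:, None]
    return FeatureSequence(data=z.T, fs=FS_FEATURES, trial=segment.trial,
                           task=segment.task, sentence_index=segment.sentence_index,
                           mean=mean, sd=sd)


def extract_features(dataset: SyntheticDataset, tasks: tuple[str, ...] | None = None,
                     exclude_electrodes: tuple[int, ...] = ()) -> list[FeatureSequence]:
    """Full pipeline: trim -> resample/notch -> high-gamma envelope features."""
    return [
        highgamma_features(resample_and_notch(seg))
        for seg in trim_segments(dataset, tasks, exclude_electrodes)
    ]


def write_features(features: list[FeatureSequence], path: str | Path) -> None:
    """Persist features as /features/<trial>_<task> with a filter-spec sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("features")
        for feat in features:
            d = grp.create_dataset(f"{feat.trial}_{feat.task}",
                                   data=feat.data.astype(np.float32))
            d.attrs["fs"] = feat.fs
            d.attrs["sentence_index"] = feat.sentence_index
    spec = {
        "bands_hz": [list(b) for b in HIGH_GAMMA_BANDS],
        "fir_taps": FIR_TAPS,
        "notch_hz": list(NOTCH_FREQS),
        "notch_q": NOTCH_Q,
        "fs_intermediate": FS_INTERMEDIATE,
        "fs_features": FS_FEATURES,
    }
    path.with_suffix(".filters.json").write_text(json.dumps(spec, indent=2))
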