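"""Synthetic multichannel ECoG-like recordings with planted token codes.

The generator emulates the study conditions the decoder is meant to face:
80 trials x {overt, covert, perception} tasks, 8 three-token sentences,
3.5 s sentence segments at 1200 Hz over 32 electrodes.  Background activity
is pink (1/f) noise plus 50/100 Hz line noise, so the notch and band-pass
stages downstream are exercised realistically.  Token information is planted
as amplitude-modulated 70-150 Hz band-limited bursts on token-specific
electrode subsets, one token per third of the sentence interval (the pacing
of the constant-rate text highlighting).

The covert condition implements the motor-hypothesis premise that inner
speech is an attenuated, spatially less focal copy of overt speech: covert
bursts are scaled by ``covert_gain``, ride on electrode sets that share a
fraction ``overlap`` (alpha) of their electrodes with the overt sets, and
leak at reduced gain onto neighboring electrodes.  With ``overlap=1`` and
``covert_gain=1`` the overt and covert generative laws coincide.

Every quantity is drawn from a single seeded generator, so a dataset is
bitwise reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isinf

import numpy as np
from scipy import signal

from .corpus import SentenceSpec, TrialSchedule, build_sentences

TASKS = ("overt", "covert", "perception")
HIGH_GAMMA_BAND = (70.0, 150.0)

#: fundamental frequency (Hz) of the harmonic complex voicing each token
TOKEN_F0 = {0: 110.0, 1: 139.0, 2: 175.0, 3: 220.0, 4: 277.0, 5: 349.0}


@dataclass(frozen=True)
class SynthConfig:
    n_electrodes: int = 32
    fs_raw: float = 1200.0
    fs_audio: float = 16000.0
    segment_duration: float = 3.5  # sentence interval, s
    dummy_duration: float = 0.6  # lead-in discarded by trimming, s
    pad_duration: float = 0.25  # recording padding around the events, s
    electrodes_per_token: int = 2
    overlap: float = 1.0  # alpha: fraction of covert electrodes shared with overt
    covert_gain: float = 0.7  # covert burst amplitude relative to overt
    covert_spread: float = 0.3  # leak gain onto electrodes adjacent to covert sets
    snr_db: float = 10.0  # burst band power over background band power in-window
    line_noise_amp: float = 0.5  # 50 Hz amplitude relative to background RMS
    seed: int = 0
    informative_sets: dict[int, tuple[int, ...]] | None = None  # overt sets; default derived

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError(f"overlap must be in [0, 1], got {self.overlap}")
        if not (0.0 < self.covert_gain <= 1.0):
            raise ValueError(f"covert_gain must be in (0, 1], got {self.covert_gain}")
        if self.informative_sets is not None:
            if any(len(v) == 0 for v in self.informative_sets.values()):
                raise ValueError("informative sets must be non-empty")
            flat = [e for v in self.informative_sets.values() for e in v]
            if flat and (min(flat) < 0 or max(flat) >= self.n_electrodes):
                raise ValueError("informative sets exceed electrode range")


def overt_electrode_sets(config: SynthConfig) -> dict[int, tuple[int, ...]]:
    """Token -> electrode subset carrying that token's burst in overt speech."""
    if config.informative_sets is not None:
        return dict(config.informative_sets)
    m = config.electrodes_per_token
    if 12 * m > config.n_electrodes:
        raise ValueError("not enough electrodes for disjoint overt and covert banks")
    return {t: tuple(range(m * t, m * t + m)) for t in range(6)}


def covert_electrode_sets(config: SynthConfig) -> dict[int, tuple[int, ...]]:
    """Covert sets: keep round(alpha*m) overt electrodes per token, replace the
    rest with electrodes from a disjoint covert-only bank."""
    overt = overt_electrode_sets(config)
    m = config.electrodes_per_token
    alt_base = 6 * m  # covert-only bank starts after the overt bank
    covert = {}
    for t, electrodes in overt.items():
        keep = int(round(config.overlap * len(electrodes)))
        alt = tuple(alt_base + m * t + j for j in range(len(electrodes) - keep))
        covert[t] = tuple(electrodes[:keep]) + alt
    return covert


@dataclass
class TrialRecording:
    trial: int
    task: str
    sentence_index: int
    signal: np.ndarray  # (n_electrodes, n_samples)
    fs: float
    dummy_interval: tuple[float, float]  # seconds within this recording
    sentence_interval: tuple[float, float]
    audio: np.ndarray | None = None  # overt & perception tasks only
    fs_audio: float = 0.0


@dataclass
class SyntheticDataset:
    config: SynthConfig
    schedule: TrialSchedule
    sentences: list[SentenceSpec]
    recordings: list[TrialRecording]
    overt_sets: dict[int, tuple[int, ...]] = field(default_factory=dict)
    covert_sets: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def get(self, trial: int, task: str) -> TrialRecording:
        for rec in self.recordings:
            if rec.trial == trial and rec.task == task:
                return rec
        raise KeyError(f"no recording for trial={trial} task={task!r}")

    @property
    def n_trials(self) -> int:
        return self.schedule.n_trials


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """1/f-power noise, unit RMS per channel (FFT spectral shaping)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _band_noise(rng: np.random.Generator, n_samples: int, fs: float) -> np.ndarray:
    """Unit-RMS noise band-limited to the high-gamma band."""
    taps = signal.firwin(257, HIGH_GAMMA_BAND, pass_zero="bandpass", fs=fs)
    x = signal.filtfilt(taps, [1.0], rng.standard_normal(n_samples + 1024))[512:-512]
    return x / x.std()


def _burst_envelope(n_samples: int) -> np.ndarray:
    """Tukey window: near-flat power within the token window, tapered edges."""
    return signal.windows.tukey(n_samples, alpha=0.25)


def _background_band_power(config: SynthConfig, rng: np.random.Generator) -> float:
    """Welch estimate of the background's high-gamma band power (per channel),
    used to calibrate the planted burst amplitude to ``snr_db``."""
    n = int(10.0 * config.fs_raw)
    bg = pink_noise(rng, 1, n)[0]
    f, pxx = signal.welch(bg, fs=config.fs_raw, nperseg=2048)
    band = (f >= HIGH_GAMMA_BAND[0]) & (f <= HIGH_GAMMA_BAND[1])
    return float(np.trapezoid(pxx[band], f[band]))


def generate_audio(sentence: SentenceSpec, fs_audio: float,
                   segment_duration: float = 3.5,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthesize a sentence waveform as three equal-duration harmonic
    complexes, one per token, with token-specific fundamentals and
    formant-like spectral envelopes so MFCC trajectories discriminate tokens.
    """
    if fs_audio < 8000:
        raise ValueError(f"fs_audio must be >= 8000 Hz, got {fs_audio}")
    rng = rng or np.random.default_rng(0)
    n_per_token = int(round(segment_duration / 3 * fs_audio))
    pieces = []
    for slot, token in enumerate(sentence.scored_tokens):
        t = np.arange(n_per_token) / fs_audio
        f0 = TOKEN_F0[token]
        wave = np.zeros(n_per_token)
        for h in range(1, 7):
            # formant-like envelope: peak harmonic depends on the token
            weight = np.exp(-0.5 * ((h - (1 + token % 3)) / 1.2) ** 2)
            wave += weight * np.sin(2 * np.pi * f0 * h * t + rng.uniform(0, 2 * np.pi))
        wave *= signal.windows.tukey(n_per_token, alpha=0.1)
        wave += 0.01 * rng.standard_normal(n_per_token)
        pieces.append(wave / np.abs(wave).max())
    audio = np.concatenate(pieces)
    n_total = int(round(segment_duration * fs_audio))
    return audio[:n_total] if audio.size >= n_total else np.pad(audio, (0, n_total - audio.size))


def _plant_bursts(sig: np.ndarray, sentence: SentenceSpec, sets: dict[int, tuple[int, ...]],
                  gain: float, spread: float, burst_rms: float,
                  sent_slice: slice, fs: float, rng: np.random.Generator) -> None:
    """Add token bursts in place on ``sig`` within the sentence interval."""
    if burst_rms <= 0:
        return
    n_sent = sent_slice.stop - sent_slice.start
    third = n_sent // 3
    k = sig.shape[0]
    for slot, token in enumerate(sentence.scored_tokens):
        a = sent_slice.start + slot * third
        b = a + third
        env = _burst_envelope(b - a)
        for e in sets[token]:
            burst = _band_noise(rng, b - a, fs) * env
            # normalize realized power so the in-window SNR is exact
            burst *= burst_rms * gain / burst.std()
            sig[e, a:b] += burst
            if spread > 0:
                for nb in ((e - 1) % k, (e + 1) % k):
                    sig[nb, a:b] += spread * burst


def generate_dataset(config: SynthConfig, schedule: TrialSchedule) -> SyntheticDataset:
    """Generate the full overt/covert/perception recording set for a schedule.

    Deterministic given ``config.seed``: identical configs produce bitwise
    identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    sentences = build_sentences()
    overt_sets = overt_electrode_sets(config)
    covert_sets = covert_electrode_sets(config)

    fs = config.fs_raw
    n_pad = int(config.pad_duration * fs)
    n_dummy = int(config.dummy_duration * fs)
    n_sent = int(config.segment_duration * fs)
    n_total = 2 * n_pad + n_dummy + n_sent
    dummy_iv = (n_pad / fs, (n_pad + n_dummy) / fs)
    sent_iv = ((n_pad + n_dummy) / fs, (n_pad + n_dummy + n_sent) / fs)
    sent_slice = slice(n_pad + n_dummy, n_pad + n_dummy + n_sent)

    if isinf(config.snr_db) and config.snr_db < 0:
        burst_rms = 0.0
    else:
        p_bg = _background_band_power(config, np.random.default_rng(config.seed + 987))
        burst_rms = float(np.sqrt(p_bg * 10.0 ** (config.snr_db / 10.0)))

    recordings: list[TrialRecording] = []
    t_axis = np.arange(n_total) / fs
    for trial, sent_idx in enumerate(schedule.sentence_indices):
        sentence = sentences[sent_idx]
        audio = generate_audio(sentence, config.fs_audio, config.segment_duration, rng)
        for task in TASKS:
            sig = pink_noise(rng, config.n_electrodes, n_total)
            phases = rng.uniform(0, 2 * np.pi, size=(config.n_electrodes, 2))
            sig += config.line_noise_amp * np.sin(2 * np.pi * 50.0 * t_axis + phases[:, :1])
            sig += 0.5 * config.line_noise_amp * np.sin(2 * np.pi * 100.0 * t_axis + phases[:, 1:])
            if task == "overt":
                _plant_bursts(sig, sentence, overt_sets, 1.0, 0.0, burst_rms,
                              sent_slice, fs, rng)
            elif task == "covert":
                _plant_bursts(sig, sentence, covert_sets, config.covert_gain,
                              config.covert_spread, burst_rms, sent_slice, fs, rng)
            else:  # perception: background plus weak token-independent bursts
                weak = 0.1 * burst_rms
                if weak > 0:
                    env = _burst_envelope(n_sent)
                    for e in range(config.n_electrodes - 4, config.n_electrodes):
                        sig[e, sent_slice] += _band_noise(rng, n_sent, fs) * env * weak
            recordings.append(
                TrialRecording(
                    trial=trial,
                    task=task,
                    sentence_index=sent_idx,
                    signal=sig.astype(np.float64),
                    fs=fs,
                    dummy_interval=dummy_iv,
                    sentence_interval=sent_iv,
                    audio=audio if task in ("overt", "perception") else None,
                    fs_audio=config.fs_audio if task in ("overt", "perception") else 0.0,
                )
            )
    return SyntheticDataset(
        config=config,
        schedule=schedule,
        sentences=sentences,
        recordings=recordings,
        overt_sets=overt_sets,
        covert_sets=covert_sets,
    )
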