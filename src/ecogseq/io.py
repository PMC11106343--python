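"""HDF5 container for raw recordings, triggers, and audio.

Layout::

    /raw/<trial>_<task>          float64 (n_electrodes, n_samples)
    /audio/<trial>_<task>        float64 waveform (overt & perception only)
    /triggers                    table (trial, task, label, t_start, t_end)
    /meta                        JSON-encoded config attributes

WAV sidecar export and an EDF reader (for real recordings) map into the same
in-memory dataset structure the synthetic generator produces.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from io import BytesIO
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .corpus import TrialSchedule, build_sentences
from .synth import SynthConfig, SyntheticDataset, TrialRecording


def write_container(dataset: SyntheticDataset, path: str | Path,
                    wav_sidecars: bool = False) -> None:
    path = Path(path)
    rows = []
    with h5py.File(path, "w") as f:
        raw = f.create_group("raw")
        aud = f.create_group("audio")
        for rec in dataset.recordings:
            key = f"{rec.trial}_{rec.task}"
            d = raw.create_dataset(key, data=rec.signal)
            d.attrs["fs"] = rec.fs
            d.attrs["sentence_index"] = rec.sentence_index
            rows.append((rec.trial, rec.task, "dummy", *rec.dummy_interval))
            rows.append((rec.trial, rec.task, "sentence", *rec.sentence_interval))
            if rec.audio is not None:
                a = aud.create_dataset(key, data=rec.audio)
                a.attrs["fs"] = rec.fs_audio
                if wav_sidecars:
                    wav = (np.clip(rec.audio, -1, 1) * 32767).astype(np.int16)
                    wavfile.write(path.parent / f"{path.stem}_{key}.wav",
                                  int(rec.fs_audio), wav)
        trig = pd.DataFrame(rows, columns=["trial", "task", "label", "t_start", "t_end"])
        f.create_dataset("triggers", data=trig.to_csv(index=False).encode())
        meta = {
            "config": asdict(dataset.config),
            "schedule": list(dataset.schedule.sentence_indices),
            "schedule_seed": dataset.schedule.seed,
            "overt_sets": {str(k): list(v) for k, v in dataset.overt_sets.items()},
            "covert_sets": {str(k): list(v) for k, v in dataset.covert_sets.items()},
        }
        f.create_dataset("meta", data=json.dumps(meta).encode())


def read_container(path: str | Path) -> SyntheticDataset:
    with h5py.File(path, "r") as f:
        meta = json.loads(bytes(f["meta"][()]).decode())
        cfg_dict = meta["config"]
        if cfg_dict.get("informative_sets") is not None:
            cfg_dict["informative_sets"] = {
                int(k): tuple(v) for k, v in cfg_dict["informative_sets"].items()
            }
        config = SynthConfig(**cfg_dict)
        schedule = TrialSchedule(
            sentence_indices=tuple(meta["schedule"]), seed=meta["schedule_seed"]
        )
        trig = pd.read_csv(BytesIO(bytes(f["triggers"][()])))
        recordings = []
        for key, d in f["raw"].items():
            trial_s, task = key.split("_", 1)
            trial = int(trial_s)
            sub = trig[(trig.trial == trial) & (trig.task == task)]
            dummy = sub[sub.label == "dummy"].iloc[0]
            sent = sub[sub.label == "sentence"].iloc[0]
            audio = fs_audio = None
            if key in f["audio"]:
                audio = f["audio"][key][()]
                fs_audio = float(f["audio"][key].attrs["fs"])
            recordings.append(
                TrialRecording(
                    trial=trial,
                    task=task,
                    sentence_index=int(d.attrs["sentence_index"]),
                    signal=d[()],
                    fs=float(d.attrs["fs"]),
                    dummy_interval=(float(dummy.t_start), float(dummy.t_end)),
                    sentence_interval=(float(sent.t_start), float(sent.t_end)),
                    audio=audio,
                    fs_audio=fs_audio or 0.0,
                )
            )
    recordings.sort(key=lambda r: (r.trial, r.task))
    return SyntheticDataset(
        config=config,
        schedule=schedule,
        sentences=build_sentences(),
        recordings=recordings,
        overt_sets={int(k): tuple(v) for k, v in meta["overt_sets"].items()},
        covert_sets={int(k): tuple(v) for k, v in meta["covert_sets"].items()},
    )


def read_edf(path: str | Path, triggers: pd.DataFrame,
             schedule: TrialSchedule, config: SynthConfig) -> SyntheticDataset:
    """Adapter for real EDF recordings: slices a continuous EDF into per-trial
    recordings using an external trigger table with columns
    (trial, task, label, t_start, t_end) in seconds.  Requires ``mne``.
    """
    import mne  # optional dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sig = raw.get_data()
    fs = float(raw.info["sfreq"])
    recordings = []
    for (trial, task), sub in triggers.groupby(["trial", "task"]):
        dummy = sub[sub.label == "dummy"].iloc[0]
        sent = sub[sub.label == "sentence"].iloc[0]
        a = int(dummy.t_start * fs)
        b = int(sent.t_end * fs)
        recordings.append(
            TrialRecording(
                trial=int(trial),
                task=str(task),
                sentence_index=schedule.sentence_indices[int(trial)],
                signal=sig[:, a:b],
                fs=fs,
                dummy_interval=(0.0, float(dummy.t_end - dummy.t_start)),
                sentence_interval=(
                    float(sent.t_start - dummy.t_start),
                    float(sent.t_end - dummy.t_start),
                ),
            )
        )
    recordings.sort(key=lambda r: (r.trial, r.task))
    return SyntheticDataset(
        config=config, schedule=schedule, sentences=build_sentences(),
        recordings=recordings,
    )
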