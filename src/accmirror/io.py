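"""File formats: schedule/spike/ethogram TSVs, binary+JSON array containers,
continuous recordings, and WAV.

Arrays are stored as raw little-endian float32 with a JSON sidecar carrying
shape and sampling metadata; tabular data as tab-separated text. WAV goes
through :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth import AudioEnergyTrack, ContinuousRecording, Ethogram, SpikeTrain, TrialSchedule

SCHEDULE_COLUMNS = [
    "session_id",
    "trial_index",
    "condition",
    "intensity_code",
    "onset_s",
    "duration_s",
]


# -- schedules --------------------------------------------------------------

def write_schedule_tsv(schedule: TrialSchedule, path) -> None:
    df = schedule.trials.copy()
    df.insert(0, "session_id", schedule.session_id)
    df.to_csv(path, sep="\t", index=False)


def read_schedule_tsv(path) -> TrialSchedule:
    df = pd.read_csv(path, sep="\t", dtype={"intensity_code": "Int64"})
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule TSV missing columns: {sorted(missing)}")
    session_id = df["session_id"].iloc[0] if len(df) else "ShockObs"
    return TrialSchedule(session_id, df.drop(columns="session_id"))


# -- generic binary + JSON array container ---------------------------------

def write_array(path, array: np.ndarray, meta: dict | None = None) -> None:
    """Raw little-endian float32 array + ``<path>.json`` sidecar."""
    path = Path(path)
    arr = np.ascontiguousarray(array, dtype="<f4")
    arr.tofile(path)
    sidecar = {"shape": list(arr.shape), "dtype": "<f4"}
    sidecar.update(meta or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_array(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=meta.get("dtype", "<f4")).reshape(meta["shape"])
    return arr, meta


# -- spike trains -----------------------------------------------------------

def write_spikes(directory, spike_trains: list[SpikeTrain]) -> None:
    """``spikes.tsv`` plus one waveform container per unit×session."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for st in spike_trains:
        for t in st.times:
            rows.append((st.unit_id, st.session_id, t))
        if st.waveforms is not None:
            write_array(
                directory / f"waveforms_{st.unit_id}_{st.session_id}.bin",
                st.waveforms,
                {
                    "n_samples": st.waveforms.shape[1],
                    "sample_rate_hz": 32000.0,
                    "unit_id": st.unit_id,
                    "session_id": st.session_id,
                },
            )
    pd.DataFrame(rows, columns=["unit_id", "session_id", "spike_time_s"]).to_csv(
        directory / "spikes.tsv", sep="\t", index=False
    )


def read_spikes(directory) -> list[SpikeTrain]:
    directory = Path(directory)
    df = pd.read_csv(directory / "spikes.tsv", sep="\t")
    out = []
    for (uid, sess), grp in df.groupby(["unit_id", "session_id"], sort=True):
        wf_path = directory / f"waveforms_{uid}_{sess}.bin"
        wf = read_array(wf_path)[0] if wf_path.exists() else None
        out.append(
            SpikeTrain(uid, sess, np.sort(grp["spike_time_s"].to_numpy(float)), wf)
        )
    return out


# -- continuous recordings --------------------------------------------------

def write_continuous(path, rec: ContinuousRecording) -> None:
    write_array(
        path,
        rec.data,
        {
            "n_channels": rec.n_channels,
            "n_samples": rec.n_samples,
            "fs_hz": rec.fs_hz,
            "shaft_map": rec.shaft_map,
            "channel_names": rec.channel_names,
        },
    )


def read_continuous(path) -> ContinuousRecording:
    data, meta = read_array(path)
    return ContinuousRecording(
        data=data,
        fs_hz=meta["fs_hz"],
        shaft_map=meta["shaft_map"],
        channel_names=meta.get("channel_names"),
    )


# -- ethograms and head angle ----------------------------------------------

def write_ethogram(directory, etho: Ethogram) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    etho.intervals.to_csv(directory / "ethogram.tsv", sep="\t", index=False)
    etho.head_angle.to_csv(directory / "head_angle.tsv", sep="\t", index=False)


def read_ethogram(directory) -> Ethogram:
    directory = Path(directory)
    return Ethogram(
        intervals=pd.read_csv(directory / "ethogram.tsv", sep="\t"),
        head_angle=pd.read_csv(directory / "head_angle.tsv", sep="\t"),
    )


# -- audio ------------------------------------------------------------------

def write_audio_track(path, track: AudioEnergyTrack) -> None:
    write_array(
        path,
        track.energy,
        {
            "t0": float(track.times[0]) if len(track.times) else 0.0,
            "dt": track.dt,
            "freqs": track.freqs.tolist(),
        },
    )


def read_audio_track(path) -> AudioEnergyTrack:
    energy, meta = read_array(path)
    n = energy.shape[1]
    times = meta["t0"] + meta["dt"] * np.arange(n)
    return AudioEnergyTrack(times=times, freqs=np.array(meta["freqs"]), energy=energy)


def write_wav(path, samples: np.ndarray, fs_hz: int) -> None:
    wavfile.write(path, int(fs_hz), samples.astype(np.float32))


def read_wav(path) -> tuple[np.ndarray, int]:
    fs, x = wavfile.read(path)
    return np.asarray(x), fs


def render_wav_from_track(track: AudioEnergyTrack, fs_hz: int = 4000) -> np.ndarray:
    """Band-limited waveform whose short-time energy follows the track.

    Provided for format round-trips; the analysis itself operates on the
    energy matrix directly.
    """
    rng = np.random.default_rng(0)
    env = np.sqrt(track.energy.mean(axis=0))
    n = int(round((track.times[-1] + track.dt / 2) * fs_hz)) if len(track.times) else 0
    carrier = rng.standard_normal(n)
    t = np.arange(n) / fs_hz
    gain = np.interp(t, track.times, env)
    return (carrier * gain).astype(np.float32)
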