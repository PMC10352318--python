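"""Recording-session container and on-disk layout.

A session holds the aligned channels of one imaging run: ΔHbT (µM, slow
camera clock), raw EMG and hippocampal LFP (fast clock), treadmill
velocity, the stimulus onset times and the age group.  Sessions round-trip
through a directory of either HDF5 (default) or per-channel CSV files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = ["RecordingSession", "save_session", "load_session"]


@dataclass
class RecordingSession:
    hbt: np.ndarray
    fs_hbt: float
    emg: np.ndarray
    lfp: np.ndarray
    fs_raw: float
    velocity: np.ndarray
    stim_onsets: np.ndarray
    age_group: str
    duration: float
    subject_id: str = "synthetic"
    trial_s: float = 300.0  # sessions are acquired in sequential 5-min trials

    def validate(self) -> None:
        if self.fs_hbt <= 0 or self.fs_raw <= 0:
            raise ValueError("sampling rates must be positive")
        for name, trace, fs in (
            ("hbt", self.hbt, self.fs_hbt),
            ("velocity", self.velocity, self.fs_hbt),
            ("emg", self.emg, self.fs_raw),
            ("lfp", self.lfp, self.fs_raw),
        ):
            expect = int(round(self.duration * fs))
            if abs(len(trace) - expect) > fs:  # tolerate < 1 s mismatch
                raise ValueError(
                    f"channel {name!r} has {len(trace)} samples, expected ~{expect}"
                )
        onsets = np.asarray(self.stim_onsets, float)
        if len(onsets) and (np.any(np.diff(onsets) < 0)):
            raise ValueError("stimulus onsets must be sorted")
        if len(onsets) and (onsets[-1] >= self.duration or onsets[0] < 0):
            raise ValueError("stimulus onset outside the session span")

    @property
    def trial_bounds(self) -> list[tuple[float, float]]:
        """Boundaries of the sequential fixed-length trials."""
        bounds = []
        t = 0.0
        while t < self.duration:
            bounds.append((t, min(t + self.trial_s, self.duration)))
            t += self.trial_s
        return bounds


_CHANNELS = ("hbt", "emg", "lfp", "velocity")


def save_session(session: RecordingSession, path: str | Path, fmt: str = "hdf5") -> Path:
    """Write a session to ``path``/ (HDF5 single file or per-channel CSV)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs_hbt": float(session.fs_hbt),
        "fs_raw": float(session.fs_raw),
        "age_group": session.age_group,
        "duration": float(session.duration),
        "subject_id": session.subject_id,
        "trial_s": float(session.trial_s),
        "format": fmt,
    }
    (path / "session.yaml").write_text(yaml.safe_dump(meta))
    pd.DataFrame({"time_s": session.stim_onsets}).to_csv(
        path / "stimuli.csv", index=False
    )
    if fmt == "hdf5":
        with h5py.File(path / "channels.h5", "w") as h5:
            for name in _CHANNELS:
                h5.create_dataset(name, data=getattr(session, name))
    elif fmt == "csv":
        for name in _CHANNELS:
            trace = getattr(session, name)
            fs = session.fs_hbt if name in ("hbt", "velocity") else session.fs_raw
            pd.DataFrame(
                {"time_s": np.arange(len(trace)) / fs, "value": trace}
            ).to_csv(path / f"{name}.csv", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def load_session(path: str | Path) -> RecordingSession:
    path = Path(path)
    meta_file = path / "session.yaml"
    if not meta_file.exists():
        raise FileNotFoundError(f"no session metadata at {meta_file}")
    meta = yaml.safe_load(meta_file.read_text())
    stims = pd.read_csv(path / "stimuli.csv")["time_s"].to_numpy()
    channels = {}
    if meta.get("format") == "csv":
        for name in _CHANNELS:
            f = path / f"{name}.csv"
            if not f.exists():
                raise FileNotFoundError(f"missing channel file {f}")
            channels[name] = pd.read_csv(f)["value"].to_numpy()
    else:
        with h5py.File(path / "channels.h5", "r") as h5:
            for name in _CHANNELS:
                if name not in h5:
                    raise KeyError(f"missing channel {name!r} in {path}")
                channels[name] = h5[name][:]
    session = RecordingSession(
        hbt=channels["hbt"],
        emg=channels["emg"],
        lfp=channels["lfp"],
        velocity=channels["velocity"],
        fs_hbt=meta["fs_hbt"],
        fs_raw=meta["fs_raw"],
        stim_onsets=stims,
        age_group=meta["age_group"],
        duration=meta["duration"],
        subject_id=meta.get("subject_id", "unknown"),
        trial_s=meta.get("trial_s", 300.0),
    )
    session.validate()
    return session
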