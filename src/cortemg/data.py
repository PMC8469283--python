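"""Core data containers and the on-disk session layout.

A recording *session* is one treadmill day: sorted cortical spike trains,
multi-channel hindlimb EMG sampled at 1 kHz, and a gait annotation listing
the consecutive-step runs.  Sessions are stored one-per-directory as plain
UTF-8 delimited text so that every pipeline stage can be run from files:

    <session_dir>/
        spikes.tsv    unit_id <TAB> time_s
        emg.tsv       time_s <TAB> one column per muscle label
        gait.tsv      step_start_s <TAB> step_end_s <TAB> run_id
        runs.tsv      run_id <TAB> termination_reason
        manifest.txt  key=value lines (session_id, day_index, phase, ...)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The six high-SNR muscles: left/right soleus, left/right rectus femoris,
#: right tibialis anterior, left semitendinosus.
MUSCLES = ("LS", "RS", "LRF", "RRF", "RTA", "LST")

def muscle_side(label: str) -> str:
    """Return ``"ipsi"`` for right-hindlimb muscles, ``"contra"`` for left."""
    if label.startswith("R"):
        return "ipsi"
    if label.startswith("L"):
        return "contra"
    raise ValueError(f"unknown muscle label {label!r}")


@dataclass
class SpikeTrain:
    """Sorted spike event times (seconds) of one putative single unit."""

    unit_id: int
    channel_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (
            np.any(np.diff(self.times) <= 0) or self.times[0] < 0
        ):
            raise ValueError(
                f"unit {self.unit_id}: spike times must be nonnegative and "
                "strictly increasing"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class EMGTrace:
    """One muscle's EMG samples at a fixed rate (1 kHz in this study)."""

    muscle: str
    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class GaitAnnotation:
    """Step boundaries grouped into runs of consecutive walking.

    ``steps`` is an (n_steps, 2) float array of [start_s, end_s); ``run_ids``
    assigns each step to a run; ``termination_reason`` maps run_id to why the
    run ended (hindpaw drag, posture change, or end of session).
    """

    steps: np.ndarray
    run_ids: np.ndarray
    termination_reason: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float).reshape(-1, 2)
        self.run_ids = np.asarray(self.run_ids, dtype=int)
        if self.steps.shape[0] != self.run_ids.size:
            raise ValueError("steps and run_ids length mismatch")
        if self.steps.size:
            if np.any(self.steps[:, 1] <= self.steps[:, 0]):
                raise ValueError("every step must have end_s > start_s")
            if np.any(self.steps[1:, 0] < self.steps[:-1, 1] - 1e-9):
                raise ValueError("steps must be ordered and non-overlapping")

    @property
    def n_steps(self) -> int:
        return int(self.steps.shape[0])


@dataclass
class Session:
    """One recording day: spikes + EMG + gait, tagged pre/post lesion."""

    session_id: str
    day_index: int
    duration: float
    speed: float
    spike_trains: list[SpikeTrain]
    emg_traces: list[EMGTrace]
    gait: GaitAnnotation

    @property
    def phase(self) -> str:
        return "pre" if self.day_index < 0 else "post"

    @property
    def n_units(self) -> int:
        return len(self.spike_trains)

    @property
    def muscles(self) -> list[str]:
        return [t.muscle for t in self.emg_traces]


# ---------------------------------------------------------------------------
# session I/O
# ---------------------------------------------------------------------------

def write_session(session: Session, directory: str | Path) -> Path:
    """Write a session to ``directory`` in the delimited-text layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = [
        (t.unit_id, time)
        for t in session.spike_trains
        for time in t.times
    ]
    spikes = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    spikes.to_csv(directory / "spikes.tsv", sep="\t", index=False,
                  float_format="%.6f")

    if session.emg_traces:
        fs = session.emg_traces[0].sample_rate
        emg = pd.DataFrame({"time_s": session.emg_traces[0].times})
        for trace in session.emg_traces:
            emg[trace.muscle] = trace.samples
    else:
        fs = 1000.0
        emg = pd.DataFrame({"time_s": []})
    emg.to_csv(directory / "emg.tsv", sep="\t", index=False,
               float_format="%.6f")

    gait = pd.DataFrame({
        "step_start_s": session.gait.steps[:, 0],
        "step_end_s": session.gait.steps[:, 1],
        "run_id": session.gait.run_ids,
    })
    gait.to_csv(directory / "gait.tsv", sep="\t", index=False,
                float_format="%.6f")
    runs = pd.DataFrame(
        sorted(session.gait.termination_reason.items()),
        columns=["run_id", "termination_reason"],
    )
    runs.to_csv(directory / "runs.tsv", sep="\t", index=False)

    manifest = {
        "session_id": session.session_id,
        "day_index": session.day_index,
        "phase": session.phase,
        "duration_s": session.duration,
        "speed_m_per_s": session.speed,
        "emg_sample_rate_hz": fs,
        "n_units": session.n_units,
    }
    with open(directory / "manifest.txt", "w", encoding="utf-8") as fh:
        for key, value in manifest.items():
            fh.write(f"{key}={value}\n")
    return directory


def read_manifest(directory: str | Path) -> dict[str, str]:
    manifest: dict[str, str] = {}
    with open(Path(directory) / "manifest.txt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, _, value = line.partition("=")
                manifest[key] = value
    return manifest


def read_session(directory: str | Path) -> Session:
    """Read a session previously written by :func:`write_session`."""
    directory = Path(directory)
    manifest = read_manifest(directory)

    spikes = pd.read_csv(directory / "spikes.tsv", sep="\t")
    trains = []
    for unit_id, group in spikes.groupby("unit_id", sort=True):
        trains.append(SpikeTrain(
            unit_id=int(unit_id),
            channel_id=int(unit_id),
            times=np.sort(group["time_s"].to_numpy()),
        ))

    emg = pd.read_csv(directory / "emg.tsv", sep="\t")
    fs = float(manifest.get("emg_sample_rate_hz", 1000.0))
    traces = [
        EMGTrace(muscle=col, sample_rate=fs, samples=emg[col].to_numpy())
        for col in emg.columns
        if col != "time_s"
    ]

    gait_df = pd.read_csv(directory / "gait.tsv", sep="\t")
    reasons: dict[int, str] = {}
    runs_path = directory / "runs.tsv"
    if runs_path.exists():
        runs = pd.read_csv(runs_path, sep="\t")
        reasons = dict(zip(runs["run_id"].astype(int),
                           runs["termination_reason"]))
    gait = GaitAnnotation(
        steps=gait_df[["step_start_s", "step_end_s"]].to_numpy(),
        run_ids=gait_df["run_id"].to_numpy(dtype=int),
        termination_reason=reasons,
    )

    return Session(
        session_id=manifest["session_id"],
        day_index=int(manifest["day_index"]),
        duration=float(manifest["duration_s"]),
        speed=float(manifest.get("speed_m_per_s", 0.4)),
        spike_trains=trains,
        emg_traces=traces,
        gait=gait,
    )
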