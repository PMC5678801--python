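"""Plain-text interchange formats for streams, trajectories and waveforms.

All files are whitespace-separated columns with a comment header carrying
the duration, e.g. ``# T=1000.0``, so externally produced event streams
can be filtered and package outputs inspected with standard tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cascade import BumpWaveform
from .light_models import EventStream, StateTrajectory
from .snyder import FilterOutput

__all__ = [
    "write_events", "read_events",
    "write_trajectory", "read_trajectory",
    "write_waveform", "read_waveform",
    "write_bump_table", "read_bump_table",
    "write_filter_output",
]


def _read_T(path) -> float:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#") and "T=" in line:
                return float(line.split("T=")[1].split()[0])
            if line and not line.startswith("#"):
                break
    raise ValueError(f"{path}: missing '# T=<duration>' header")


def write_events(stream: EventStream, path) -> None:
    np.savetxt(path, stream.times, header=f"T={stream.T}", comments="# ")


def read_events(path) -> EventStream:
    T = _read_T(path)
    times = np.atleast_1d(np.loadtxt(path, ndmin=1))
    return EventStream(times, T)


def write_trajectory(traj: StateTrajectory, path) -> None:
    data = np.column_stack([traj.change_times, traj.states])
    np.savetxt(path, data, header=f"T={traj.T}", comments="# ",
               fmt=["%.10g", "%d"])


def read_trajectory(path) -> StateTrajectory:
    T = _read_T(path)
    data = np.loadtxt(path, ndmin=2)
    return StateTrajectory(data[:, 0], data[:, 1].astype(int), T)


def write_waveform(wave: BumpWaveform, path, table_path=None) -> None:
    np.savetxt(path, np.column_stack([wave.t_grid, wave.current]),
               header=f"T={wave.t_grid[-1]}  columns: t current", comments="# ")
    if table_path is not None:
        write_bump_table(wave.bump_table, table_path)


def read_waveform(path, table_path=None) -> BumpWaveform:
    data = np.loadtxt(path, ndmin=2)
    table = read_bump_table(table_path) if table_path else np.empty((0, 4))
    return BumpWaveform(data[:, 0], data[:, 1], table)


def write_bump_table(table: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(table).reshape(-1, 4),
               header="columns: photon_time latency amplitude width",
               comments="# ")


def read_bump_table(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2).reshape(-1, 4)


def write_filter_output(out: FilterOutput, path, tau: float | None = None) -> None:
    header = "columns: t x_hat " + " ".join(
        f"p{i}" for i in range(out.posterior.shape[1]))
    if tau is not None:
        header = f"tau={tau}\n" + header
    np.savetxt(path, np.column_stack([out.t, out.x_hat, out.posterior]),
               header=header, comments="# ")
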