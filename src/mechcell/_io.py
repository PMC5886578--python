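"""Round-trip helpers for trajectory/event CSV files."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import n_species


class _StubBatch:
    """Minimal batch facade reconstructed from an event log."""

    def __init__(self, n):
        self.n_cells = n
        self.death_time = np.full(n, np.nan)
        self.s_entry_time = np.full(n, np.nan)
        self.division_times = [[] for _ in range(n)]
        self.failed = np.zeros(n, dtype=bool)
        self.dead = np.zeros(n, dtype=bool)


class _StubRecording:
    def __init__(self, times, data, columns, batch):
        self.times = times
        self.data = data
        self.columns = columns
        self.batch = batch

    def trajectory(self, i):
        from .simulate import CellTrajectory
        b = self.batch
        return CellTrajectory(self.times, self.data, self.columns, i,
                              b.death_time[i], list(b.division_times[i]),
                              b.s_entry_time[i], bool(b.failed[i]))


def recording_from_csv(trajectories_path, events_path):
    """Rebuild a population recording from the long-format trajectory CSV
    and fate event log written by the simulation driver."""
    df = pd.read_csv(trajectories_path)
    cells = np.sort(df["cell_id"].unique())
    columns = list(df["species"].unique())
    times = np.sort(df["time_h"].unique())
    n = len(cells)
    data = np.zeros((len(times), len(columns), n), dtype=np.float32)
    t_idx = {t: i for i, t in enumerate(times)}
    c_idx = {c: i for i, c in enumerate(cells)}
    s_idx = {s: i for i, s in enumerate(columns)}
    for row in df.itertuples(index=False):
        data[t_idx[row.time_h], s_idx[row.species], c_idx[row.cell_id]] = row.amount

    batch = _StubBatch(n)
    ev = pd.read_csv(events_path)
    for row in ev.itertuples(index=False):
        i = c_idx.get(row.cell_id)
        if i is None:
            continue
        if row.event == "death":
            batch.death_time[i] = row.time_h
            batch.dead[i] = True
        elif row.event == "s_entry":
            batch.s_entry_time[i] = row.time_h
        elif row.event == "division":
            batch.division_times[i].append(row.time_h)
    return _StubRecording(times, data, columns, batch)
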