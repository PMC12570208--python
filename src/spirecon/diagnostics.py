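"""Event logging and the computational weather plot.

Long reconstructions are monitored through a plain append-only text
log: one tab-separated line per completed task, flushed immediately so
the file stays parseable after an abrupt termination at any point.  The
weather plot renders the log as one row per worker with a dot at each
task's completion time — stalled workers and I/O hiccups show up as
gaps at a glance.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["TaskEvent", "EventLog", "parse_log", "weather_plot"]


@dataclass(frozen=True)
class TaskEvent:
    """One completed processing step."""

    worker: int
    label: str
    wall_time: float      # seconds since run start
    generation: int


class EventLog:
    """Append-only tab-separated event log.

    The file is opened (and its directory required to exist) at
    construction, so unwritable paths fail before the run starts, never
    mid-run.  Each ``record`` writes one line and flushes.
    """

    def __init__(self, path, t0: float | None = None):
        self.path = path
        self._fh = open(path, "a")
        self.t0 = time.monotonic() if t0 is None else t0

    def record(self, worker: int, label: str, generation: int,
               wall_time: float | None = None) -> TaskEvent:
        if wall_time is None:
            wall_time = time.monotonic() - self.t0
        if "\t" in label or "\n" in label:
            raise ParameterError("task label must not contain tabs or newlines")
        ev = TaskEvent(worker=int(worker), label=label,
                       wall_time=float(wall_time), generation=int(generation))
        self._fh.write(f"{ev.worker}\t{ev.generation}\t{ev.label}\t{ev.wall_time:.6f}\n")
        self._fh.flush()
        return ev

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def parse_log(path) -> list[TaskEvent]:
    """Read an event log, skipping a trailing partial line if present."""
    events = []
    with open(path) as fh:
        for line in fh:
            if not line.endswith("\n"):
                break  # torn final line from an abrupt termination
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                continue
            try:
                events.append(TaskEvent(worker=int(parts[0]), generation=int(parts[1]),
                                        label=parts[2], wall_time=float(parts[3])))
            except ValueError:
                continue
    return events


def weather_plot(log_path, figure_path) -> dict:
    """Render the weather plot: one row per worker, dots at completion times.

    Returns the plotted data (worker ids and per-worker event times) so
    tests can assert on content rather than pixels.  The figure is
    written as PNG; rendering is deterministic for a fixed log.
    """
    events = parse_log(log_path)
    if not events:
        raise ParameterError(f"event log {log_path} is empty")
    workers = sorted({e.worker for e in events})
    rows = {w: sorted(e.wall_time for e in events if e.worker == w) for w in workers}

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.4 * max(len(workers), 4) + 1.5))
    for w in workers:
        ax.plot(rows[w], [w] * len(rows[w]), ".", ms=4, color="tab:green")
    ax.set_xlabel("wall time (s)")
    ax.set_ylabel("worker")
    ax.set_yticks(workers)
    ax.set_title("computational weather")
    fig.tight_layout()
    fig.savefig(figure_path, dpi=120)
    plt.close(fig)
    return {"workers": workers, "rows": rows}
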