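"""Data model, I/O and preprocessing for spike-train recordings.

A recording session is a set of multi-unit spike trains, one per recording
node (an electrode of a multi-electrode array, or a model neuron), observed
over a common window.  Files are plain delimited text with one event per
line: ``node_id<TAB or ,>time_seconds``; ``#`` starts a comment.

Observation windows are half-open ``[t_start, t_end)`` so that consecutive
windows never double-count an event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "Recording",
    "load_spike_trains",
    "save_spike_trains",
    "filter_low_activity",
    "jitter_spike_times",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one node over an observation window.

    Parameters
    ----------
    node_id
        Label of the recording node.
    times
        Spike times in seconds, nondecreasing, all within
        ``[t_start, t_end)``.
    t_start, t_end
        Observation bounds in seconds, ``t_end > t_start``.
    """

    node_id: str
    times: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", times)
        if self.t_end <= self.t_start:
            raise ValueError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )
        if times.ndim != 1:
            raise ValueError("times must be a 1-D array")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValueError(f"spike times of node {self.node_id!r} not sorted")
            if times[0] < self.t_start or times[-1] >= self.t_end:
                raise ValueError(
                    f"spike times of node {self.node_id!r} outside "
                    f"[{self.t_start}, {self.t_end})"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/second."""
        return self.n_spikes / self.duration

    def restrict(self, t_start: float, t_end: float) -> "SpikeTrain":
        """Return the train restricted to the half-open window ``[t_start, t_end)``."""
        lo = np.searchsorted(self.times, t_start, side="left")
        hi = np.searchsorted(self.times, t_end, side="left")
        return SpikeTrain(self.node_id, self.times[lo:hi], t_start, t_end)


@dataclass(frozen=True)
class Recording:
    """All spike trains of one session plus session metadata.

    ``trains`` maps node_id to :class:`SpikeTrain`; all trains share the
    same observation window and node ids are unique by construction.
    """

    culture_id: str
    day: int
    trains: Mapping[str, SpikeTrain] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", dict(self.trains))
        bounds = {(tr.t_start, tr.t_end) for tr in self.trains.values()}
        if len(bounds) > 1:
            raise ValueError(f"trains disagree on observation window: {bounds}")
        for node_id, tr in self.trains.items():
            if tr.node_id != node_id:
                raise ValueError(f"train keyed {node_id!r} has node_id {tr.node_id!r}")

    @property
    def node_ids(self) -> list[str]:
        return list(self.trains)

    @property
    def n_nodes(self) -> int:
        return len(self.trains)

    @property
    def t_start(self) -> float:
        return next(iter(self.trains.values())).t_start

    @property
    def t_end(self) -> float:
        return next(iter(self.trains.values())).t_end

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains.values())

    def __getitem__(self, node_id: str) -> SpikeTrain:
        return self.trains[node_id]

    def __iter__(self) -> Iterator[SpikeTrain]:
        return iter(self.trains.values())

    def __len__(self) -> int:
        return len(self.trains)


class SpikeFileError(ValueError):
    """Raised when a spike-train text file cannot be parsed."""


def _natural_key(node_id: str):
    try:
        return (0, float(node_id), node_id)
    except ValueError:
        return (1, 0.0, node_id)


def load_spike_trains(
    path: str | Path,
    t_start: float,
    t_end: float,
    *,
    culture_id: str | None = None,
    day: int = 0,
    sample_rate: float | None = None,
) -> Recording:
    """Load a delimited spike file into a :class:`Recording`.

    Each non-comment line holds ``node_id<TAB or , or space>time``.  Times
    are seconds unless ``sample_rate`` is given, in which case the second
    column is an integer sample index converted by ``time = sample /
    sample_rate``.  Events outside the half-open window ``[t_start, t_end)``
    are dropped (the count is logged).
    """
    path = Path(path)
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    ids: list[str] = []
    times: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for delim in ("\t", ","):
                if delim in line:
                    parts = line.split(delim)
                    break
            else:
                parts = line.split()
            if len(parts) != 2:
                raise SpikeFileError(
                    f"{path}:{lineno}: expected 'node_id<delim>time', got {raw!r}"
                )
            node_id, t_str = parts[0].strip(), parts[1].strip()
            try:
                t = float(t_str)
            except ValueError as exc:
                raise SpikeFileError(
                    f"{path}:{lineno}: unparseable time {t_str!r}"
                ) from exc
            if sample_rate is not None:
                t /= sample_rate
            ids.append(node_id)
            times.append(t)
    if not ids:
        raise SpikeFileError(f"{path}: no spike events found")

    id_arr = np.asarray(ids)
    t_arr = np.asarray(times, dtype=np.float64)
    in_window = (t_arr >= t_start) & (t_arr < t_end)
    n_dropped = int((~in_window).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d events outside [%g, %g)", path, n_dropped, t_start, t_end
        )
    id_arr, t_arr = id_arr[in_window], t_arr[in_window]

    trains = {}
    for node_id in sorted(set(id_arr), key=_natural_key):
        node_times = np.sort(t_arr[id_arr == node_id])
        trains[node_id] = SpikeTrain(node_id, node_times, t_start, t_end)
    return Recording(culture_id or path.stem, day, trains)


def save_spike_trains(rec: Recording, path: str | Path) -> None:
    """Write a recording in the two-column tab-delimited text format."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# culture={rec.culture_id} day={rec.day} "
                 f"window=[{rec.t_start!r},{rec.t_end!r})\n")
        for tr in rec:
            for t in tr.times:
                fh.write(f"{tr.node_id}\t{float(t)!r}\n")


def filter_low_activity(rec: Recording, min_spikes: int = 100) -> Recording:
    """Drop trains with fewer than ``min_spikes`` events.

    The default of 100 follows standard practice for MEA recordings, where
    near-silent electrodes carry too few events for history-based
    estimation.  The comparison is strict: a train with exactly
    ``min_spikes`` events is retained.
    """
    if min_spikes < 0:
        raise ValueError("min_spikes must be nonnegative")
    kept = {nid: tr for nid, tr in rec.trains.items() if tr.n_spikes >= min_spikes}
    removed = sorted(set(rec.trains) - set(kept), key=_natural_key)
    if removed:
        logger.info(
            "filter_low_activity(min_spikes=%d): removed nodes %s",
            min_spikes,
            removed,
        )
    if not kept:
        raise ValueError(
            f"all {rec.n_nodes} trains fall below min_spikes={min_spikes}; "
            "nothing left to analyse"
        )
    return replace(rec, trains=kept)


def jitter_spike_times(
    rec: Recording,
    half_width: float = 20e-6,
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Add independent Uniform(−half_width, +half_width) noise to every spike.

    Acquisition hardware quantises spike times to the sampling grid (40 µs
    at 25 kHz), so raw interspike intervals are integer multiples of the
    grid step.  Nearest-neighbour estimators must not see those exact ties;
    dithering by half a grid step (the default ±20 µs) removes them without
    moving any spike by more than the quantisation error.  Spikes jittered
    across the window edge are clipped inside it.  Exact ties within a
    train (zero probability, but guarded) are re-drawn.
    """
    if half_width < 0:
        raise ValueError("half_width must be nonnegative")
    if half_width == 0:
        return rec
    rng = np.random.default_rng(seed)
    trains = {}
    for nid, tr in rec.trains.items():
        t = tr.times + rng.uniform(-half_width, half_width, size=tr.n_spikes)
        t = np.clip(t, tr.t_start, np.nextafter(tr.t_end, -np.inf))
        t.sort()
        # re-draw any exact ties (measure-zero, but cheap to guarantee)
        while t.size > 1 and np.any(np.diff(t) == 0):
            dup = np.flatnonzero(np.diff(t) == 0)
            t[dup] += rng.uniform(0, half_width / 2, size=dup.size)
            t = np.clip(t, tr.t_start, np.nextafter(tr.t_end, -np.inf))
            t.sort()
        trains[nid] = SpikeTrain(nid, t, tr.t_start, tr.t_end)
    return replace(rec, trains=trains)


def recording_from_arrays(
    spikes: Iterable[tuple[str, np.ndarray]],
    t_start: float,
    t_end: float,
    culture_id: str = "recording",
    day: int = 0,
) -> Recording:
    """Build a :class:`Recording` from ``(node_id, times)`` pairs."""
    trains = {
        nid: SpikeTrain(nid, np.sort(np.asarray(t, dtype=np.float64)), t_start, t_end)
        for nid, t in spikes
    }
    return Recording(culture_id, day, trains)
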