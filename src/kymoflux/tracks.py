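"""Track and force-trace containers plus CSV I/O.

A :class:`Track` is one particle's time-ordered positions along the tether,
as exported per (track id, color channel) by kymograph particle trackers.
Unobserved frames (excitation gaps, tracking dropouts bridged during gap
connection) are kept in place with ``observed_mask`` False so that frame
indexing stays uniform at the instrument line time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig

#: canonical CSV schema written by :func:`write_tracks`
NATIVE_COLUMNS = ["track_id", "channel", "time_s", "position_um", "observed"]

#: column mapping for CSVs in the shape of public kymograph-tracking deposits
DRYAD_COLUMN_MAP = {
    "track id": "track_id",
    "channel": "channel",
    "time (s)": "time_s",
    "position (um)": "position_um",
}


@dataclass
class Track:
    track_id: str
    channel: str  # {"red", "green"}
    times: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # um along tether
    observed_mask: np.ndarray | None = None
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.observed_mask is None:
            self.observed_mask = np.ones(self.times.shape, dtype=bool)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if not (len(self.times) == len(self.positions) == len(self.observed_mask)):
            raise ValueError("times, positions and observed_mask must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")
        obs = self.positions[self.observed_mask]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError(f"track {self.track_id}: observed positions must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) > 1 else 0.0

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, positions) restricted to observed frames."""
        m = self.observed_mask
        return self.times[m], self.positions[m]

    def with_positions(self, positions: np.ndarray) -> "Track":
        return Track(self.track_id, self.channel, self.times.copy(),
                     np.asarray(positions, dtype=float),
                     self.observed_mask.copy(), dict(self.source))


@dataclass
class ForceTrace:
    """Force-clamp distance-time record used for nucleosome counting."""

    times: np.ndarray  # s
    distance: np.ndarray  # nm
    force: np.ndarray | None = None  # pN
    clamp_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("force trace times must be strictly increasing")
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)

    def clamped(self) -> "ForceTrace":
        """Restrict to the clamp window if one is set."""
        if self.clamp_window is None:
            return self
        lo, hi = self.clamp_window
        m = (self.times >= lo) & (self.times <= hi)
        return ForceTrace(self.times[m], self.distance[m],
                          None if self.force is None else self.force[m], None)


def read_tracks(path: str | Path, dialect: str = "native",
                cfg: SimulationConfig | None = None) -> list[Track]:
    """Read a track-table CSV into one :class:`Track` per (track_id, channel).

    ``dialect="native"`` expects the schema written by :func:`write_tracks`;
    ``dialect="dryad"`` applies :data:`DRYAD_COLUMN_MAP` (configurable by
    editing that mapping) to tracker-deposit column names.
    """
    df = pd.read_csv(path)
    if dialect == "dryad":
        df = df.rename(columns={k: v for k, v in DRYAD_COLUMN_MAP.items() if k in df.columns})
    elif dialect != "native":
        raise ValueError(f"unknown dialect: {dialect!r}")
    missing = {"track_id", "time_s", "position_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "channel" not in df.columns:
        df["channel"] = "red"
    if "observed" not in df.columns:
        df["observed"] = True

    tracks = []
    for (tid, chan), grp in df.groupby(["track_id", "channel"], sort=True):
        t = grp["time_s"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(
                f"{path}: non-monotone time in track {tid!r}/{chan!r} at row {grp.index[bad]}")
        tracks.append(Track(str(tid), str(chan), t,
                            grp["position_um"].to_numpy(dtype=float),
                            grp["observed"].to_numpy(dtype=bool),
                            source={"path": str(path), "dialect": dialect}))
    return tracks


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write tracks to the native CSV schema (header always emitted)."""
    frames = [
        pd.DataFrame({
            "track_id": tr.track_id, "channel": tr.channel,
            "time_s": tr.times, "position_um": tr.positions,
            "observed": tr.observed_mask,
        })
        for tr in tracks
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=NATIVE_COLUMNS)
    out.to_csv(path, index=False)


def read_force_trace(path: str | Path,
                     clamp_window: tuple[float, float] | None = None) -> ForceTrace:
    """Read a force trace CSV: time_s, distance_nm[, force_pN]."""
    df = pd.read_csv(path)
    missing = {"time_s", "distance_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    force = df["force_pN"].to_numpy(dtype=float) if "force_pN" in df.columns else None
    return ForceTrace(df["time_s"].to_numpy(dtype=float),
                      df["distance_nm"].to_numpy(dtype=float), force, clamp_window)


def connect_track_gaps(tracks: list[Track], max_gap_frames: int = 8,
                       max_jump: float = 0.4,
                       line_time: float | None = None) -> list[Track]:
    """Merge track fragments split by short tracking dropouts.

    Fragments from the same kymograph/channel whose temporal gap is at most
    ``max_gap_frames`` frames and whose positional jump is at most
    ``max_jump`` um are joined; the gap is filled with linearly interpolated,
    unobserved frames.  When two candidates fall within tolerance the one
    with the smaller positional discrepancy wins (deterministic after a
    stable sort by start time).
    """
    if not tracks:
        return []
    if line_time is None:
        dts = [np.median(np.diff(tr.times)) for tr in tracks if len(tr) > 1]
        line_time = float(np.median(dts)) if dts else 1.0

    frags = sorted(tracks, key=lambda tr: tr.times[0])
    merged: list[Track] = []
    current = frags[0]
    pool = frags[1:]
    while pool:
        # candidate fragments reachable from the current tail
        t_end, x_end = current.times[-1], current.positions[-1]
        cands = []
        for i, fr in enumerate(pool):
            gap = (fr.times[0] - t_end) / line_time - 1.0
            if -0.5 <= gap <= max_gap_frames + 0.5 and abs(fr.positions[0] - x_end) <= max_jump:
                cands.append((abs(fr.positions[0] - x_end), i))
        if not cands:
            merged.append(current)
            current = pool.pop(0)
            continue
        cands.sort()
        if len(cands) > 1:
            warnings.warn(
                f"ambiguous gap merge after track {current.track_id}: "
                f"{len(cands)} candidates, nearest-in-position chosen")
        _, idx = cands[0]
        nxt = pool.pop(idx)
        n_gap = max(0, int(round((nxt.times[0] - t_end) / line_time)) - 1)
        gap_t = t_end + line_time * np.arange(1, n_gap + 1)
        gap_x = np.interp(gap_t, [t_end, nxt.times[0]], [x_end, nxt.positions[0]])
        current = Track(
            current.track_id, current.channel,
            np.concatenate([current.times, gap_t, nxt.times]),
            np.concatenate([current.positions, gap_x, nxt.positions]),
            np.concatenate([current.observed_mask, np.zeros(n_gap, bool), nxt.observed_mask]),
            dict(current.source, merged_with=nxt.track_id),
        )
    merged.append(current)
    return merged
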