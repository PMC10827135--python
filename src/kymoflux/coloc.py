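"""Two-color colocalization analysis.

Remodeler-remodeler encounters are detected by comparing the smoothed
inter-particle separation to a displacement threshold derived from each
molecule's mean diffusion coefficient under an independent-Brownian-motion
model (d = x1 + x2 with x_i = sqrt(2 D_i dt)), then classified as short
colocalizations (collision followed by recoil), long colocalizations
(transient co-diffusion) or rare bypass events (the particles cross and
continue).  Remodeler-nucleosome colocalization uses a piecewise-constant
nucleosome position map extended across pulsed-excitation dark gaps from
the last visible signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import (DEFAULT_LINE_TIME, DEFAULT_LONG_MIN, DEFAULT_NUC_RADIUS_BP,
                     DEFAULT_SMOOTH_SPAN, SimulationConfig)
from .diffusion import rolling_window_D
from .tracks import Track

KIND_SHORT = "short_coloc"
KIND_LONG = "long_coloc"
KIND_BYPASS = "bypass"


@dataclass
class ThresholdModel:
    mean_D_1: float  # um^2/s
    mean_D_2: float
    dt: float  # s
    x1: float  # um, per-molecule frame displacement scale
    x2: float
    d_threshold: float  # um, = x1 + x2

    def __post_init__(self) -> None:
        if not np.isclose(self.d_threshold, self.x1 + self.x2):
            raise ValueError("d_threshold must equal x1 + x2")


@dataclass
class EncounterEvent:
    kind: str  # short_coloc | long_coloc | bypass | nucleosome_coloc
    t_start: float
    t_end: float
    duration: float
    mean_separation: float  # um
    track_ids: tuple
    metrics: dict = field(default_factory=dict)


def colocalization_threshold(mean_D_1: float, mean_D_2: float,
                             dt: float = DEFAULT_LINE_TIME,
                             safety_factor: float = 1.0,
                             fixed_threshold: float | None = None) -> ThresholdModel:
    """Distance threshold for two independently diffusing molecules.

    x_i = sqrt(2 mean_D_i dt) is the RMS 1D Brownian frame displacement of
    molecule i, and the colocalization threshold is d = x1 + x2 (scaled by
    ``safety_factor``).  ``fixed_threshold`` overrides the model with an
    empirically determined constant (e.g. 0.31 um) while keeping the
    per-molecule scales for the classification tests.
    """
    if mean_D_1 < 0 or mean_D_2 < 0 or dt <= 0:
        raise ValueError("require mean D >= 0 and dt > 0")
    x1 = np.sqrt(2.0 * mean_D_1 * dt)
    x2 = np.sqrt(2.0 * mean_D_2 * dt)
    if fixed_threshold is not None:
        scale = fixed_threshold / (x1 + x2) if (x1 + x2) > 0 else 0.0
        return ThresholdModel(mean_D_1, mean_D_2, dt,
                              x1 * scale if (x1 + x2) > 0 else fixed_threshold / 2,
                              x2 * scale if (x1 + x2) > 0 else fixed_threshold / 2,
                              fixed_threshold)
    d = safety_factor * (x1 + x2)
    return ThresholdModel(mean_D_1, mean_D_2, dt, safety_factor * x1, safety_factor * x2, d)


def threshold_from_tracks(track1: Track, track2: Track,
                          dt: float = DEFAULT_LINE_TIME, **kw) -> ThresholdModel:
    """Threshold from the mean rolling-window D of each molecule."""
    D1 = float(np.nanmean(rolling_window_D(track1)))
    D2 = float(np.nanmean(rolling_window_D(track2)))
    return colocalization_threshold(D1, D2, dt, **kw)


def _smooth(x: np.ndarray, span: int) -> np.ndarray:
    """Gaussian smoothing over a ~span-frame window (sigma = span/4)."""
    if span <= 1:
        return x
    return gaussian_filter1d(x, sigma=span / 4.0, mode="nearest", truncate=2.0)


def _overlap_frames(track1: Track, track2: Track):
    """Common time grid and co-observed positions of two tracks."""
    t1 = np.round(track1.times / 1e-9).astype(np.int64)
    t2 = np.round(track2.times / 1e-9).astype(np.int64)
    common, i1, i2 = np.intersect1d(t1, t2, return_indices=True)
    if common.size == 0:
        return None
    m = track1.observed_mask[i1] & track2.observed_mask[i2]
    return track1.times[i1], track1.positions[i1], track2.positions[i2], m


def detect_colocalized_frames(track1: Track, track2: Track, threshold: ThresholdModel,
                              smooth_span: int = DEFAULT_SMOOTH_SPAN) -> list[tuple[int, int]]:
    """Maximal runs of co-observed frames with separation below threshold.

    Both trajectories are Gaussian-smoothed over ``smooth_span`` exposure
    points before the per-frame separation test.  Returns half-open frame
    index ranges into the common time grid (symmetric in track order).
    """
    ov = _overlap_frames(track1, track2)
    if ov is None:
        return []
    t, x1, x2, obs = ov
    s1, s2 = _smooth(x1, smooth_span), _smooth(x2, smooth_span)
    below = (np.abs(s1 - s2) <= threshold.d_threshold) & obs
    intervals = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(below)))
    return intervals


def _segment_D(x: np.ndarray, dt: float) -> float:
    """Apparent 1D diffusion coefficient of a short signal from its
    single-frame increments: D = var(dx) / (2 dt)."""
    if len(x) < 2:
        return np.inf
    dx = np.diff(x)
    return float(np.mean(dx * dx) / (2.0 * dt))


def classify_encounter(interval: tuple[int, int], track1: Track, track2: Track,
                       threshold: ThresholdModel, long_min: int = DEFAULT_LONG_MIN,
                       smooth_span: int = DEFAULT_SMOOTH_SPAN) -> EncounterEvent | None:
    """Classify one colocalized interval as short or long.

    An interval longer than ``long_min`` exposures is automatically long.
    Shorter intervals go through two validation tests, in order: (1) if the
    separation displacement across the interval exceeds the threshold
    model's expected displacement the event is long; (2) if the local
    apparent diffusion coefficient of the separation over the entry-exit
    segment exceeds the pair's mean D the collision was a fast graze ->
    short, otherwise long.  (Bypass is detected separately and takes
    precedence over both.)
    """
    a, b = interval
    if b - a < 1:
        return None
    ov = _overlap_frames(track1, track2)
    t, x1, x2, _ = ov
    dt = float(np.median(np.diff(t))) if len(t) > 1 else threshold.dt
    # detection used the smoothed trajectories; the validation metrics use
    # the raw separation so smoothing does not deflate local displacements
    sep_raw = np.abs(x1 - x2)
    dur_frames = b - a
    metrics = {"frames": dur_frames}
    if dur_frames > long_min:
        kind = KIND_LONG
    else:
        disp = abs(sep_raw[b - 1] - sep_raw[a])
        metrics["separation_displacement"] = disp
        if disp > threshold.d_threshold:
            kind = KIND_LONG
        else:
            # entry-exit segment: the interval plus two frames of context on
            # each side, so the approach into and exit out of the threshold
            # band contribute to the local displacement estimate
            lo, hi = max(0, a - 2), min(len(sep_raw), b + 2)
            local_D = _segment_D(sep_raw[lo:hi], dt)
            # a diffusive graze moves the separation with D1+D2, twice the
            # per-molecule average it is compared against; co-diffusion
            # moves it with ~0
            mean_D = 0.5 * (threshold.mean_D_1 + threshold.mean_D_2)
            metrics["local_D"] = local_D
            metrics["mean_D"] = mean_D
            kind = KIND_SHORT if local_D > mean_D else KIND_LONG
    return EncounterEvent(kind, float(t[a]), float(t[b - 1]),
                          float(t[b - 1] - t[a] + dt), float(sep_raw[a:b].mean()),
                          (track1.track_id, track2.track_id), metrics)


def detect_bypass(track1: Track, track2: Track, intervals: list[tuple[int, int]],
                  flank: int = 5, smooth_span: int = DEFAULT_SMOOTH_SPAN
                  ) -> list[tuple[int, int]]:
    """Intervals in which the two particles crossed (bypass events).

    An interval is a bypass when the sign of (x1 - x2), averaged over
    ``flank`` smoothed frames before versus after the interval, flips, and
    both tracks persist at least ``flank`` frames on each side.
    """
    ov = _overlap_frames(track1, track2)
    if ov is None:
        return []
    _, x1, x2, _ = ov
    diff = _smooth(x1, smooth_span) - _smooth(x2, smooth_span)
    out = []
    for a, b in intervals:
        if a < flank or b + flank > len(diff):
            continue  # insufficient flanking frames
        before = np.mean(diff[a - flank:a])
        after = np.mean(diff[b:b + flank])
        if np.sign(before) != 0 and np.sign(after) == -np.sign(before):
            out.append((a, b))
    return out


def classify_encounters(track1: Track, track2: Track, threshold: ThresholdModel,
                        long_min: int = DEFAULT_LONG_MIN,
                        smooth_span: int = DEFAULT_SMOOTH_SPAN) -> list[EncounterEvent]:
    """Full two-color pipeline: detect intervals, classify, flag bypass."""
    intervals = detect_colocalized_frames(track1, track2, threshold, smooth_span)
    bypass = set(detect_bypass(track1, track2, intervals, smooth_span=smooth_span))
    events = []
    for iv in intervals:
        ev = classify_encounter(iv, track1, track2, threshold, long_min, smooth_span)
        if ev is None:
            continue
        if iv in bypass:
            ev.kind = KIND_BYPASS
        events.append(ev)
    return events


@dataclass
class NucleosomePositionMap:
    """Piecewise-constant nucleosome positions extended across dark gaps."""

    entries: dict  # id -> {"times", "positions", "stable"}
    t_span: tuple[float, float] | None = None

    def position_at(self, nuc_id: str, t: np.ndarray) -> np.ndarray:
        e = self.entries[nuc_id]
        idx = np.searchsorted(e["times"], t, side="right") - 1
        idx = np.clip(idx, 0, len(e["times"]) - 1)  # back-fill before first signal
        return e["positions"][idx]

    @property
    def stable_ids(self) -> list:
        return [k for k, e in self.entries.items() if e["stable"]]


def build_nucleosome_map(nucleosome_tracks: list[Track],
                         stability_sd_um: float = 0.144,
                         links: list[tuple[str, str]] | None = None
                         ) -> NucleosomePositionMap:
    """Nucleosome position map from (pulsed-excitation) green tracks.

    Each nucleosome's position is held at the last visible fluorescence
    signal through dark pulses and after photobleaching.  Signals whose
    observed positional SD exceeds ``stability_sd_um`` (default: twice the
    ~72 nm localization precision) are flagged unstable and excluded, and
    the exclusion propagates through ``links`` (pairs of signal ids judged
    to be the same physical nucleosome).
    """
    entries = {}
    for tr in nucleosome_tracks:
        t_obs, x_obs = tr.observed()
        if len(t_obs) == 0:
            continue
        stable = bool(np.std(x_obs) <= stability_sd_um)
        entries[tr.track_id] = {"times": t_obs, "positions": x_obs, "stable": stable}
    # propagate instability through linked signals until stable
    if links:
        changed = True
        while changed:
            changed = False
            for a, b in links:
                if a in entries and b in entries:
                    if entries[a]["stable"] != entries[b]["stable"]:
                        entries[a]["stable"] = entries[b]["stable"] = False
                        changed = True
    if not any(e["stable"] for e in entries.values()):
        warnings.warn("no stable nucleosome signals; map is empty")
    t_span = None
    if entries:
        t_span = (min(float(e["times"][0]) for e in entries.values()),
                  max(float(e["times"][-1]) for e in entries.values()))
    return NucleosomePositionMap(entries, t_span)


def remodeler_nucleosome_coloc(remodeler: Track, nuc_map: NucleosomePositionMap,
                               radius_um: float | None = None,
                               cfg: SimulationConfig | None = None,
                               radius_bp: float = DEFAULT_NUC_RADIUS_BP
                               ) -> list[EncounterEvent]:
    """Runs of frames with the remodeler within ``radius`` of a nucleosome.

    The radius defaults to 500 bp converted through the configured
    um-per-bp constant.  Each maximal run is one event tagged with the
    nucleosome id; these dwells feed the dwell module as non-diffusive
    on-nucleosome residences when the diffusion profile concurs.
    """
    if radius_um is None:
        cfg = cfg or SimulationConfig()
        radius_um = radius_bp * cfg.um_per_bp
    events = []
    t, x = remodeler.observed()
    if len(t) == 0:
        return events
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    for nid in nuc_map.stable_ids:
        nx = nuc_map.position_at(nid, t)
        near = np.abs(x - nx) <= radius_um
        start = None
        for i, b in enumerate(np.append(near, False)):
            if b and start is None:
                start = i
            elif not b and start is not None:
                events.append(EncounterEvent(
                    "nucleosome_coloc", float(t[start]), float(t[i - 1]),
                    float(t[i - 1] - t[start] + dt),
                    float(np.mean(np.abs(x[start:i] - nx[start:i]))),
                    (remodeler.track_id, nid)))
                start = None
    events.sort(key=lambda e: e.t_start)
    return events


def event_proportions(events: list[EncounterEvent]) -> dict:
    """Event-type proportions (the pie-chart accounting of encounter kinds)."""
    if not events:
        return {}
    kinds, counts = np.unique([e.kind for e in events], return_counts=True)
    total = counts.sum()
    return {k: int(c) / int(total) for k, c in zip(kinds, counts)}
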