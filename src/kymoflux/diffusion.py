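"""Rolling-window MSD diffusion analysis.

Instantaneous diffusion coefficients are estimated on 20-frame rolling
sub-trajectories: the mean squared displacement (MSD) over the first five
time lags is fit by ordinary least squares (with intercept, which absorbs
the static localization-error offset) and D = slope / (2 d) with d = 1
dimension.  Windows are then classified against immobile-control-derived
thresholds (non-diffusive D < 0.01 um^2/s; low < 0.04; high >= 0.04),
runs shorter than 10 windows are dissolved as spurious detections, and
state durations / fractions are reported per track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import (D_THRESHOLD_HIGH, D_THRESHOLD_NON, DEFAULT_FIT_POINTS,
                     DEFAULT_MIN_RUN, DEFAULT_SMOOTH_SPAN, DEFAULT_WINDOW)
from .tracks import Track

STATE_NON = "non"
STATE_LOW = "low"
STATE_HIGH = "high"
STATE_UNCLASSIFIED = "unclassified"


@dataclass
class MsdCurve:
    lags: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.msd[self.n_pairs > 0] < -1e-15):
            raise ValueError("msd must be >= 0")


@dataclass
class DiffusionProfile:
    window_centers: np.ndarray  # frame index of each window center
    D_window: np.ndarray  # um^2/s, raw (unsmoothed) estimates
    state_per_window: np.ndarray  # labels after smoothing + thresholding
    segments: list  # (state, start_window, end_window) half-open
    state_durations: dict  # state -> total s
    state_fractions: dict  # state -> fraction of classified time
    line_time: float = 0.0


def _frame_grid(track: Track) -> tuple[np.ndarray, np.ndarray, float]:
    """Positions and observed mask on a uniform frame grid."""
    t = track.times
    if len(t) < 2:
        return track.positions.copy(), track.observed_mask.copy(), 1.0
    dt = float(np.median(np.diff(t)))
    idx = np.round((t - t[0]) / dt).astype(int)
    n = idx[-1] + 1
    x = np.full(n, np.nan)
    obs = np.zeros(n, dtype=bool)
    x[idx] = track.positions
    obs[idx] = track.observed_mask
    return x, obs, dt


def compute_msd(track: Track, max_lag: int) -> MsdCurve:
    """Time-averaged MSD per frame lag, counting only observed pairs."""
    x, obs, dt = _frame_grid(track)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed frames")
    n = len(x)
    if max_lag >= n:
        warnings.warn(f"max_lag {max_lag} >= track length {n}; truncating")
        max_lag = n - 1
    msd = np.zeros(max_lag)
    n_pairs = np.zeros(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        valid = obs[:-k] & obs[k:]
        n_pairs[k - 1] = valid.sum()
        if n_pairs[k - 1]:
            d = x[k:][valid] - x[:-k][valid]
            msd[k - 1] = np.mean(d * d)
    return MsdCurve(dt * np.arange(1, max_lag + 1), msd, n_pairs)


def rolling_window_D(track: Track, window: int = DEFAULT_WINDOW,
                     fit_points: int = DEFAULT_FIT_POINTS, dims: int = 1) -> np.ndarray:
    """Per-window diffusion coefficients, um^2/s (NaN where unclassifiable).

    For each window position (stride 1 frame), the MSD over the first
    ``fit_points`` lags is fit by OLS with intercept; D = slope / (2 dims),
    floored at 0.  Windows in which any of the first ``fit_points`` lags has
    no observed pair are returned NaN (unclassified).
    """
    if window < fit_points + 1:
        raise ValueError("window must be at least fit_points + 1")
    x, obs, dt = _frame_grid(track)
    n = len(x)
    if n < window:
        raise ValueError(f"track length {n} shorter than window {window}")
    n_win = n - window + 1
    xf = np.where(obs, x, 0.0)

    # per-lag squared displacements and validity, then windowed means via cumsum
    msd = np.empty((n_win, fit_points))
    ok = np.ones(n_win, dtype=bool)
    for k in range(1, fit_points + 1):
        d2 = (xf[k:] - xf[:-k]) ** 2
        valid = (obs[:-k] & obs[k:]).astype(float)
        d2 = d2 * valid
        # window starting at w uses pair start indices w .. w+window-1-k
        m = window - k
        csum_d = np.concatenate([[0.0], np.cumsum(d2)])
        csum_v = np.concatenate([[0.0], np.cumsum(valid)])
        sums = csum_d[m:m + n_win] - csum_d[:n_win]
        cnts = csum_v[m:m + n_win] - csum_v[:n_win]
        with np.errstate(invalid="ignore", divide="ignore"):
            msd[:, k - 1] = sums / cnts
        ok &= cnts > 0

    lags = dt * np.arange(1, fit_points + 1)
    lc = lags - lags.mean()
    denom = float(np.dot(lc, lc))
    slope = (msd @ lc) / denom  # OLS slope with intercept, per window
    D = np.maximum(slope / (2.0 * dims), 0.0)
    D[~ok] = np.nan
    return D


def classify_windows(D: np.ndarray,
                     thresholds: tuple[float, float] = (D_THRESHOLD_NON, D_THRESHOLD_HIGH)
                     ) -> np.ndarray:
    """Threshold per-window D into non/low/high states.

    D < thresholds[0] -> non; thresholds[0] <= D < thresholds[1] -> low;
    D >= thresholds[1] -> high (the boundary value is assigned upward).
    NaN -> unclassified.
    """
    D = np.asarray(D, dtype=float)
    if D.size == 0:
        raise ValueError("empty D series")
    lo, hi = thresholds
    labels = np.full(D.shape, STATE_UNCLASSIFIED, dtype="<U12")
    labels[D < lo] = STATE_NON
    labels[(D >= lo) & (D < hi)] = STATE_LOW
    labels[D >= hi] = STATE_HIGH
    labels[np.isnan(D)] = STATE_UNCLASSIFIED
    return labels


def smooth_positions(track: Track, span: int = DEFAULT_SMOOTH_SPAN) -> Track:
    """Centered moving average with shrinking symmetric end windows.

    Mirrors the classic moving-average smoother: interior points average
    ``span`` neighbours; near the ends the window shrinks to stay symmetric
    (the first and last points are returned unchanged).
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be odd and >= 1")
    if span == 1:
        return track.with_positions(track.positions.copy())
    x = track.positions
    n = len(x)
    h = span // 2
    y = x.astype(float).copy()
    if n >= span:
        kernel = np.full(span, 1.0 / span)
        y[h:n - h] = np.convolve(x, kernel, mode="valid")
    for i in range(min(h, n)):
        w = min(i, n - 1 - i)
        y[i] = x[i - w:i + w + 1].mean()
        y[n - 1 - i] = x[n - 1 - i - w:n - i + w].mean()
    return track.with_positions(y)


def _runs(labels: np.ndarray) -> list[list]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([labels[start], start, i])
            start = i
    return runs


def segment_states(labels: np.ndarray, min_run: int = DEFAULT_MIN_RUN,
                   line_time: float = 1.0) -> tuple[list, dict, dict]:
    """Group equal-label windows into segments and dissolve short runs.

    Maximal runs of identical labels form segments; any run shorter than
    ``min_run`` windows is dissolved into the flanking segment with the
    longer duration (ties go to the earlier segment).  Returns
    ``(segments, durations_s, fractions)`` with half-open
    ``(state, start, end)`` window index ranges.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    runs = _runs(labels)
    if all(r[2] - r[1] < min_run for r in runs) and len(runs) > 1:
        vals, counts = np.unique(labels, return_counts=True)
        modal = vals[np.argmax(counts)]
        warnings.warn("all runs shorter than min_run; collapsing to modal label")
        runs = [[modal, 0, len(labels)]]
    else:
        while len(runs) > 1:
            lengths = [r[2] - r[1] for r in runs]
            short = [i for i, L in enumerate(lengths) if L < min_run]
            if not short:
                break
            i = min(short, key=lambda j: (lengths[j], j))
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i + 1 < len(runs) else None
            if left is not None and (right is None
                                     or (left[2] - left[1]) >= (right[2] - right[1])):
                target = left
            else:
                target = right
            runs[i][0] = target[0]
            # merge adjacent runs with now-equal labels
            j = 0
            new_runs = []
            for r in runs:
                if new_runs and new_runs[-1][0] == r[0]:
                    new_runs[-1][2] = r[2]
                else:
                    new_runs.append(r)
            runs = new_runs

    segments = [(r[0], r[1], r[2]) for r in runs]
    durations: dict = {}
    for state, a, b in segments:
        durations[state] = durations.get(state, 0.0) + (b - a) * line_time
    classified = sum(v for k, v in durations.items() if k != STATE_UNCLASSIFIED)
    fractions = {k: (v / classified if classified > 0 else 0.0)
                 for k, v in durations.items() if k != STATE_UNCLASSIFIED}
    return segments, durations, fractions


def diffusion_profile(track: Track, window: int = DEFAULT_WINDOW,
                      fit_points: int = DEFAULT_FIT_POINTS,
                      thresholds: tuple[float, float] = (D_THRESHOLD_NON, D_THRESHOLD_HIGH),
                      min_run: int = DEFAULT_MIN_RUN,
                      smooth_span: int = DEFAULT_SMOOTH_SPAN) -> DiffusionProfile:
    """Two-pass per-track analysis: raw D estimates, smoothed classification.

    D values are estimated on the raw positions; the state classification
    (and the segments/durations/fractions derived from it) uses positions
    smoothed over ``smooth_span`` frames, which suppresses spurious state
    transitions from localization noise.  ``smooth_span=1`` disables
    smoothing (appropriate for noise-free data).
    """
    _, _, dt = _frame_grid(track)
    D_raw = rolling_window_D(track, window, fit_points)
    smoothed = smooth_positions(track, smooth_span) if smooth_span > 1 else track
    D_cls = rolling_window_D(smoothed, window, fit_points) if smooth_span > 1 else D_raw
    labels = classify_windows(D_cls, thresholds)
    segments, durations, fractions = segment_states(labels, min_run, dt)
    centers = np.arange(len(D_raw)) + (window - 1) / 2.0
    return DiffusionProfile(centers, D_raw, labels, segments, durations, fractions, dt)


@dataclass
class PrecisionEstimate:
    s: float  # Gaussian fit SD, um
    N: float  # photon count
    sigma0: float  # um


def localization_precision(s: float, N: float) -> PrecisionEstimate:
    """Localization precision sigma0 = s / sqrt(N) from the Gaussian-fit SD
    ``s`` and photon count ``N`` (the standard shot-noise-limited relation).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if s <= 0:
        raise ValueError("s must be > 0")
    return PrecisionEstimate(s, N, s / np.sqrt(N))


def non_diffusive_dwells(profile: DiffusionProfile) -> np.ndarray:
    """Durations (s) of non-diffusive segments, for dwell-time fitting."""
    return np.array([(b - a) * profile.line_time
                     for state, a, b in profile.segments if state == STATE_NON])
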