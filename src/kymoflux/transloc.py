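"""ATP-dependent processive translocation analysis.

Directed-motion intervals are found by penalized piecewise-linear
changepoint segmentation (exact dynamic program over least-squares segment
costs with a BIC-like penalty), each segment is fit by ordinary least
squares, and admission filters reject segments that cannot be
distinguished from the no-hydrolysis control: events shorter than 5 s,
spanning less than 300 bp, or with R^2 below 0.5 are excluded.  Admitted
segments feed direction-change counting, per-frame trace fragmentation
(1D search / static engagement / translocation) and push-pull calls
relative to the diffusive approach direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import (MIN_TRANSLOC_BP, MIN_TRANSLOC_R2, MIN_TRANSLOC_S,
                     SimulationConfig)
from .coloc import EncounterEvent
from .diffusion import DiffusionProfile, STATE_NON
from .tracks import Track

LABEL_SEARCH = "search_1D"
LABEL_ENGAGED = "engaged_static"
LABEL_TRANSLOC = "translocating"


@dataclass
class TranslocationSegment:
    t_start: float
    t_end: float
    speed_bp_s: float  # signed
    distance_bp: float  # signed, = speed * duration (from the fit)
    r_squared: float
    admitted: bool
    rejection_reason: str = ""
    track_ids: tuple = ()
    speed_se_bp_s: float = np.nan

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def direction(self) -> int:
        return int(np.sign(self.speed_bp_s)) if self.speed_bp_s else 0


def _segment_cost_arrays(t: np.ndarray, x: np.ndarray):
    """Prefix sums enabling O(1) residual sum of squares of an OLS line fit
    on any index range [i, j)."""
    z = np.zeros(1)
    return {
        "n": np.concatenate([z, np.cumsum(np.ones_like(t))]),
        "t": np.concatenate([z, np.cumsum(t)]),
        "x": np.concatenate([z, np.cumsum(x)]),
        "tt": np.concatenate([z, np.cumsum(t * t)]),
        "xx": np.concatenate([z, np.cumsum(x * x)]),
        "tx": np.concatenate([z, np.cumsum(t * x)]),
    }


def _rss(c, i, j):
    """RSS of the OLS line on [i, j) for all i in the given array, fixed j."""
    n = c["n"][j] - c["n"][i]
    st = c["t"][j] - c["t"][i]
    sx = c["x"][j] - c["x"][i]
    stt = c["tt"][j] - c["tt"][i]
    sxx = c["xx"][j] - c["xx"][i]
    stx = c["tx"][j] - c["tx"][i]
    var_t = stt - st * st / n
    cov = stx - st * sx / n
    ss_x = sxx - sx * sx / n
    with np.errstate(invalid="ignore", divide="ignore"):
        rss = ss_x - np.where(var_t > 0, cov * cov / np.maximum(var_t, 1e-300), 0.0)
    return np.maximum(rss, 0.0)


def piecewise_linear_changepoints(t: np.ndarray, x: np.ndarray,
                                  penalty: float | str = "auto",
                                  min_size: int = 8) -> list[int]:
    """Optimal changepoints of a piecewise-linear fit (penalized DP).

    Minimizes sum of per-segment OLS residual sums of squares plus
    ``penalty`` per additional segment.  ``penalty="auto"`` uses a BIC-like
    value 4 sigma^2 ln n, with sigma estimated robustly from first
    differences (MAD-based, insensitive to the linear trend itself).
    Returns interior breakpoint indices (segment boundaries).
    """
    n = len(t)
    if n < 2 * min_size:
        return []
    if penalty == "auto":
        dx = np.diff(x)
        sigma = 1.4826 * np.median(np.abs(dx - np.median(dx))) / np.sqrt(2.0)
        sigma = max(sigma, 1e-6)
        penalty = 4.0 * sigma * sigma * np.log(n)
    c = _segment_cost_arrays(t, x)
    best = np.full(n + 1, np.inf)
    best[0] = -penalty  # first segment is free of penalty
    prev = np.zeros(n + 1, dtype=int)
    starts_all = np.arange(0, n + 1)
    for j in range(min_size, n + 1):
        i = starts_all[:j - min_size + 1]
        cand = best[i] + _rss(c, i, j) + penalty
        k = int(np.argmin(cand))
        best[j] = cand[k]
        prev[j] = i[k]
    cps = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            cps.append(int(i))
        j = i
    return sorted(cps)


def _ols_segment(t: np.ndarray, x: np.ndarray):
    """Slope (um/s), its SE, intercept, and R^2 of an OLS line fit."""
    tc = t - t.mean()
    var_t = float(np.dot(tc, tc))
    if var_t == 0:
        return 0.0, np.inf, float(x.mean()), 0.0
    slope = float(np.dot(tc, x - x.mean())) / var_t
    pred = x.mean() + slope * tc
    rss = float(np.sum((x - pred) ** 2))
    tss = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = max(len(t) - 2, 1)
    se = np.sqrt(rss / dof / var_t)
    return slope, se, float(x.mean() - slope * t.mean()), r2


def segment_speeds(track: Track, cfg: SimulationConfig | None = None,
                   penalty: float | str = "auto",
                   min_bp: float = MIN_TRANSLOC_BP, min_s: float = MIN_TRANSLOC_S,
                   min_r2: float = MIN_TRANSLOC_R2, min_size: int = 8,
                   manual_changepoints: list[float] | None = None
                   ) -> list[TranslocationSegment]:
    """Piecewise-linear speed segmentation with admission filters.

    Candidate constant-speed segments come from the penalized changepoint
    fit (or from ``manual_changepoints``, boundary times in seconds, for a
    hand-segmented input path); each is fit by OLS and admitted only if it
    spans at least ``min_bp`` base pairs, lasts at least ``min_s`` seconds,
    and has R^2 of at least ``min_r2``.  No-hydrolysis control traces
    (static colocalization + noise) processed identically yield no admitted
    segments.
    """
    cfg = cfg or SimulationConfig()
    t, x = track.observed()
    if len(t) < 2 or (t[-1] - t[0]) < min_s:
        return []
    if manual_changepoints is not None:
        cps = [int(np.searchsorted(t, cp)) for cp in sorted(manual_changepoints)]
        cps = [c for c in cps if 0 < c < len(t)]
    else:
        cps = piecewise_linear_changepoints(t, x, penalty, min_size)
    bounds = [0] + cps + [len(t)]
    segments = []
    for a, b in zip(bounds, bounds[1:]):
        ts, xs = t[a:b], x[a:b]
        if len(ts) < 2:
            continue
        slope_um, se_um, _, r2 = _ols_segment(ts, xs)
        duration = float(ts[-1] - ts[0])
        speed_bp = slope_um / cfg.um_per_bp
        dist_bp = speed_bp * duration
        reasons = []
        if abs(dist_bp) < min_bp:
            reasons.append(f"distance<{min_bp:g}bp")
        if duration < min_s:
            reasons.append(f"duration<{min_s:g}s")
        if r2 < min_r2:
            reasons.append(f"r2<{min_r2:g}")
        segments.append(TranslocationSegment(
            float(ts[0]), float(ts[-1]), speed_bp, dist_bp, r2,
            admitted=not reasons, rejection_reason=";".join(reasons),
            track_ids=(track.track_id,), speed_se_bp_s=se_um / cfg.um_per_bp))
    return segments


def detect_direction_changes(segments: list[TranslocationSegment]) -> tuple[int, list[float]]:
    """Count sign flips between consecutive admitted segments of one event.

    Returns (count, boundary times of the flips).  Speed changes without a
    sign change do not count.
    """
    adm = [s for s in segments if s.admitted]
    changes = []
    for s1, s2 in zip(adm, adm[1:]):
        if s1.direction and s2.direction and s1.direction != s2.direction:
            changes.append(s2.t_start)
    return len(changes), changes


@dataclass
class TraceFragmentation:
    """Per-frame behavioral labels and the ordered segment/transition list."""

    times: np.ndarray
    labels: np.ndarray  # per-frame {search_1D, engaged_static, translocating}
    segments: list  # ordered (label, t_start, t_end)

    @property
    def transitions(self) -> list[tuple[str, str, float]]:
        return [(a[0], b[0], b[1]) for a, b in zip(self.segments, self.segments[1:])]


def fragment_trace(track: Track, profile: DiffusionProfile | None,
                   encounters: list[EncounterEvent],
                   segments: list[TranslocationSegment],
                   min_run: int = 5) -> TraceFragmentation:
    """Label every frame as 1D search, static engagement, or translocation.

    Precedence: translocating (inside an admitted segment) over
    engaged_static (nucleosome-colocalized) over search_1D (everything
    else).  Label runs shorter than ``min_run`` frames (localization-noise
    flicker across the colocalization radius) are dissolved into the longer
    flanking run.  A translocating frame outside any colocalization is
    still labeled translocating, with a consistency warning.
    """
    t = track.times
    labels = np.full(len(t), LABEL_SEARCH, dtype="<U16")
    coloc = np.zeros(len(t), dtype=bool)
    for ev in encounters:
        coloc |= (t >= ev.t_start) & (t <= ev.t_end)
    labels[coloc] = LABEL_ENGAGED
    transloc = np.zeros(len(t), dtype=bool)
    for seg in segments:
        if seg.admitted:
            transloc |= (t >= seg.t_start) & (t <= seg.t_end)
    if np.any(transloc & ~coloc) and encounters:
        warnings.warn("translocating frames outside any colocalization interval")
    labels[transloc] = LABEL_TRANSLOC

    if min_run > 1 and len(labels) > min_run:
        from .diffusion import _runs
        runs = _runs(labels)
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
                runs[i][0] = left[0]
            else:
                runs[i][0] = right[0]
            merged = []
            for r in runs:
                if merged and merged[-1][0] == r[0]:
                    merged[-1][2] = r[2]
                else:
                    merged.append(r)
            runs = merged
        for lab, a, b in runs:
            labels[a:b] = lab

    segs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append((str(labels[start]), float(t[start]), float(t[i - 1])))
            start = i
    return TraceFragmentation(t, labels, segs)


@dataclass
class PushPullCall:
    approach_direction: int  # +-1, 0 when unavailable
    translocation_direction: int
    call: str  # push | pull | undefined
    scenario: str = ""  # which search/engage/translocate ordering applied


def _net_direction(track: Track, t_lo: float, t_hi: float, n_frames: int = 20,
                   tail: bool = True) -> int:
    """Sign of the displacement trend over the first/last ``n_frames``
    observed frames of [t_lo, t_hi] (OLS slope of smoothed positions)."""
    t, x = track.observed()
    m = (t >= t_lo) & (t <= t_hi)
    ts, xs = t[m], x[m]
    if len(xs) < 2:
        return 0
    from .coloc import _smooth
    xs = _smooth(xs, 5)
    sl = slice(-n_frames, None) if tail else slice(None, n_frames)
    ts, xs = ts[sl], xs[sl]
    tc = ts - ts.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0:
        return 0
    return int(np.sign(np.dot(tc, xs - xs.mean()) / denom))


def classify_push_pull(track: Track, frag: TraceFragmentation,
                       segments: list[TranslocationSegment],
                       approach_frames: int = 20) -> PushPullCall:
    """Push/pull call: translocation direction vs 1D-approach direction.

    The approach direction is the sign of the net smoothed displacement
    over the final ``approach_frames`` (default 20, ~0.85 s, the rolling-window span) observed frames of the search
    segment adjacent to the translocation (directly, or across one
    engaged_static segment).  When the search segment instead *follows*
    the translocation (disengagement), the initial frames are used with
    the sign inverted.  push = same direction; pull = opposite.
    """
    adm = [s for s in segments if s.admitted]
    if not adm:
        return PushPullCall(0, 0, "undefined", "no_translocation")
    seg = adm[0]
    tdir = seg.direction
    frag_idx = [i for i, (lab, a, b) in enumerate(frag.segments)
                if lab == LABEL_TRANSLOC and b >= seg.t_start and a <= seg.t_end]
    if not frag_idx or tdir == 0:
        return PushPullCall(0, tdir, "undefined", "no_translocation")
    i = frag_idx[0]

    def seek(direction: int) -> int | None:
        j = i + direction
        hops = 0
        while 0 <= j < len(frag.segments) and hops < 2:
            lab = frag.segments[j][0]
            if lab == LABEL_SEARCH:
                return j
            if lab != LABEL_ENGAGED:
                return None
            j += direction
            hops += 1
        return None

    j = seek(-1)
    if j is not None:
        _, a, b = frag.segments[j]
        adir = _net_direction(track, a, b, approach_frames, tail=True)
        scenario = "search_then_translocate"
    else:
        j = seek(+1)
        if j is None:
            return PushPullCall(0, tdir, "undefined", "no_adjacent_search")
        _, a, b = frag.segments[j]
        adir = -_net_direction(track, a, b, approach_frames, tail=False)
        scenario = "translocate_then_disengage"
    if adir == 0:
        return PushPullCall(0, tdir, "undefined", scenario)
    call = "push" if adir == tdir else "pull"
    return PushPullCall(adir, tdir, call, scenario)
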