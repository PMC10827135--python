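"""Ground-truth-labeled synthetic data generator.

Emulates the statistical structure of single-particle kymograph data from
chromatin remodelers diffusing on a stretched DNA tether: state-switching
1D Brownian motion with three diffusion levels, exponential state/bound
lifetimes, two-color encounters (recoil, co-diffusion, bypass), pulsed
excitation and photobleaching, piecewise-linear ATP-driven translocation at
tens of bp/s, and force-clamp extension traces with discrete ~25 nm
nucleosome-unwrapping steps.  Every simulator returns a
:class:`GroundTruth` sidecar so each downstream analysis is testable by
parameter recovery.

What this generator does *not* emulate: photon-level image formation (no
PSF, no shot noise beyond per-frame Gaussian localization error), sequence-
dependent DNA affinity, and 3D rebinding kinetics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .config import SimulationConfig, rng_for
from .tracks import ForceTrace, Track


@dataclass
class DiffusionStateModel:
    """Three-level diffusion model: non / low / high diffusive states.

    States switch as a continuous-time Markov chain with the given mean
    lifetimes; on leaving a state, the next one is drawn from the
    row-stochastic ``transition_matrix`` (diagonal ignored/zero).
    """

    state_names: tuple[str, ...] = ("non", "low", "high")
    D_values: tuple[float, ...] = (0.002, 0.02, 0.06)  # um^2/s
    mean_lifetimes: tuple[float, ...] = (2.0, 1.5, 1.5)  # s
    transition_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.state_names)
        if self.transition_matrix is None:
            # uniform jump to any other state
            m = np.full((n, n), 1.0 / (n - 1)) if n > 1 else np.ones((1, 1))
            if n > 1:
                np.fill_diagonal(m, 0.0)
            self.transition_matrix = m
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (n, n):
            raise ValueError("transition_matrix shape must match number of states")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0):
            raise ValueError("transition_matrix rows must sum to 1")
        if any(d < 0 for d in self.D_values):
            raise ValueError("D_values must be >= 0")
        if any(t <= 0 for t in self.mean_lifetimes):
            raise ValueError("mean_lifetimes must be > 0")

    @classmethod
    def single_state(cls, D: float, name: str = "single") -> "DiffusionStateModel":
        return cls(state_names=(name,), D_values=(D,), mean_lifetimes=(1e9,),
                   transition_matrix=np.ones((1, 1)))


@dataclass
class GroundTruth:
    """Hidden truth emitted alongside every simulated object."""

    state_labels: np.ndarray | None = None  # per-frame hidden state index
    events: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {"events": self.events, "params": self.params}
        if self.state_labels is not None:
            d["state_labels"] = np.asarray(self.state_labels).tolist()

        def _np(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(f"not JSON serializable: {type(o)}")

        Path(path).write_text(json.dumps(d, indent=1, default=_np))


def _markov_state_path(model: DiffusionStateModel, n_frames: int, dt: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-frame hidden state indices of the continuous-time Markov chain."""
    labels = np.empty(n_frames, dtype=int)
    n_states = len(model.state_names)
    state = int(rng.integers(n_states))
    t = 0.0
    frame = 0
    while frame < n_frames:
        dwell = rng.exponential(model.mean_lifetimes[state])
        end_frame = min(n_frames, frame + max(1, int(np.ceil(dwell / dt))))
        labels[frame:end_frame] = state
        frame = end_frame
        if n_states > 1:
            state = int(rng.choice(n_states, p=model.transition_matrix[state]))
    return labels


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions back into [lo, hi] (reflecting tether-end boundaries)."""
    if hi <= lo:
        return np.clip(x, lo, hi)
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def simulate_switching_track(model: DiffusionStateModel, cfg: SimulationConfig,
                             duration: float, start: float | None = None,
                             track_id: str = "sim", channel: str = "red",
                             rng: np.random.Generator | None = None
                             ) -> tuple[Track, GroundTruth]:
    """Simulate state-switching 1D Brownian motion on the tether.

    Per frame, x(t+dt) = x(t) + N(0, 2 D_state dt), reflected at the tether
    ends, with independent N(0, noise_sigma^2) localization error added to
    each observed position.
    """
    dt = cfg.line_time
    if duration < dt:
        raise ValueError("duration shorter than one frame")
    rng = rng if rng is not None else rng_for(cfg.seed, "switching_track")
    n = int(round(duration / dt))
    labels = _markov_state_path(model, n, dt, rng)
    D = np.asarray(model.D_values, dtype=float)[labels]
    steps = rng.standard_normal(n) * np.sqrt(2.0 * D * dt)
    steps[0] = 0.0
    L = cfg.tether_length_um
    x0 = rng.uniform(0.1 * L, 0.9 * L) if start is None else float(start)
    x = _reflect(x0 + np.cumsum(steps), 0.0, L)
    obs = x + rng.standard_normal(n) * cfg.noise_sigma if cfg.noise_sigma > 0 else x
    track = Track(track_id, channel, dt * np.arange(n), obs,
                  source={"synthetic": "switching_track"})
    gt = GroundTruth(state_labels=labels, params={
        "D_values": list(model.D_values), "duration": duration, "true_positions": x})
    return track, gt


def simulate_dwells(n: int, taus, weights=None,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n i.i.d. durations from an exponential mixture."""
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    if taus.size == 0:
        raise ValueError("taus must be non-empty")
    if np.any(taus <= 0):
        raise ValueError("taus must be > 0")
    if weights is None:
        weights = np.full(taus.size, 1.0 / taus.size)
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if rng is None:
        rng = rng_for(0 if seed is None else seed, "dwells")
    comp = rng.choice(taus.size, size=n, p=weights)
    return rng.exponential(taus[comp])


def simulate_encounter_pair(cfg: SimulationConfig, scenario: str, params: dict | None = None,
                            rng: np.random.Generator | None = None
                            ) -> tuple[Track, Track, GroundTruth]:
    """Simulate a two-color 1D encounter between two diffusing particles.

    Scenarios
    ---------
    ``recoil``
        Contact, a short exponential dwell, then reflected diffusion apart
        (the particles stay on their own sides).
    ``codiffuse``
        Contact, then a shared Brownian displacement for an exponential long
        dwell, then separation.
    ``bypass``
        The particles cross and continue past each other.

    ``params``: ``dwell_mean`` (s, contact dwell), ``D`` (um^2/s per
    particle, default 0.04), ``start_separation`` (um, default 0.5),
    ``n_flank`` (approach/depart frames on each side, default 40),
    ``recoil_speed_um_s`` (recoil scenario only: the prompt approach/bounce
    drift at contact, default 3.0 -- comparable to the frame-to-frame RMS
    excursion of a high-diffusive molecule, so a collision is entered and
    left within a couple of frames as observed recoils are).
    """
    p = dict(dwell_mean=0.5, D=0.04, start_separation=0.5, n_flank=40,
             recoil_speed_um_s=3.0)
    p.update(params or {})
    if scenario not in ("recoil", "codiffuse", "bypass"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "bypass" and p["start_separation"] <= 0:
        raise ValueError("bypass scenario requires distinct initial positions")
    rng = rng if rng is not None else rng_for(cfg.seed, f"encounter_{scenario}")
    dt = cfg.line_time
    D = float(p["D"])
    sep0 = float(p["start_separation"])
    n_flank = int(p["n_flank"])
    dwell_true = float(rng.exponential(p["dwell_mean"]))
    n_dwell = max(1, int(round(dwell_true / dt)))
    n = 2 * n_flank + n_dwell

    # separation signal: the pair separation diffuses (relative diffusion
    # 2D) and is conditioned on contact only through time reversal of an
    # unconstrained walk started at the contact -- so the approach and
    # departure cross any distance threshold at genuinely diffusive speed,
    # with no slow conditioned hover near contact.  sep0 sets the scale of
    # the typical flanking separation, not an exact start point.
    sig_rel = np.sqrt(2.0 * 2.0 * D * dt)  # relative diffusion of the pair
    if scenario == "recoil":
        # prompt collision: drifted entry and bounce at recoil_speed
        drift = p["recoil_speed_um_s"] * dt
        walk_in = np.cumsum(drift + rng.standard_normal(n_flank) * sig_rel)
        approach = np.abs(walk_in[::-1])
        walk_out = np.cumsum(drift + rng.standard_normal(n_flank) * sig_rel)
        depart = np.abs(walk_out)
    else:
        walk_in = np.cumsum(rng.standard_normal(n_flank) * sig_rel)
        approach = np.abs(walk_in[::-1])
        walk_out = np.cumsum(rng.standard_normal(n_flank) * sig_rel)
        depart = np.abs(walk_out)
    contact = np.abs(rng.standard_normal(n_dwell)) * 0.02
    sep = np.concatenate([approach, contact, depart])

    # pair midpoint diffuses with D/2 (mean of two independent walkers);
    # during codiffusion the shared displacement *is* the midpoint motion
    mid_D = D / 2.0
    mid = np.cumsum(rng.standard_normal(n) * np.sqrt(2.0 * mid_D * dt))
    center = cfg.tether_length_um / 2.0
    mid += center - mid[0]

    sign = np.ones(n)
    if scenario == "bypass":
        sign[n_flank + n_dwell:] = -1.0  # particles swap sides after contact
    x1 = mid + sign * sep / 2.0
    x2 = mid - sign * sep / 2.0
    if cfg.noise_sigma > 0:
        x1 = x1 + rng.standard_normal(n) * cfg.noise_sigma
        x2 = x2 + rng.standard_normal(n) * cfg.noise_sigma

    t = dt * np.arange(n)
    tr1 = Track("enc_1", "red", t, x1, source={"synthetic": scenario})
    tr2 = Track("enc_2", "green", t, x2, source={"synthetic": scenario})
    kind = {"recoil": "short_coloc", "codiffuse": "long_coloc", "bypass": "bypass"}[scenario]
    gt = GroundTruth(events=[{
        "kind": kind, "scenario": scenario,
        "t_start": float(t[n_flank]), "t_end": float(t[n_flank + n_dwell - 1]),
        "n_dwell_frames": n_dwell, "dwell_s_true": dwell_true,
    }], params=p)
    return tr1, tr2, gt


def _brownian_bridge(a: float, b: float, n: int, step_sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """n-point Brownian bridge from a to b with per-step noise step_sigma."""
    if n == 1:
        return np.array([a])
    w = np.concatenate([[0.0], np.cumsum(rng.standard_normal(n - 1) * step_sigma)])
    frac = np.linspace(0.0, 1.0, n)
    return a + (b - a) * frac + (w - frac * w[-1])


def simulate_translocation_track(speed_bp_s: float, duration: float, cfg: SimulationConfig,
                                 direction: int = 1, changepoints: list | None = None,
                                 speeds_bp_s: list | None = None, start: float | None = None,
                                 with_nucleosome: bool = False,
                                 rng: np.random.Generator | None = None):
    """Simulate a processively translocating particle (piecewise-linear path).

    ``changepoints`` (s, strictly increasing, within ``duration``) split the
    trace; per-piece speeds come from ``speeds_bp_s`` (defaults to
    ``speed_bp_s`` for every piece).  With ``with_nucleosome=True`` a
    co-moving green-channel track is also returned (remodeler + cargo
    nucleosome share the mean path; localization noise is independent).

    Returns (track, ground_truth) or (track, nucleosome_track, ground_truth).
    """
    dt = cfg.line_time
    cps = sorted(changepoints or [])
    if any(c <= 0 or c >= duration for c in cps):
        raise ValueError("changepoints must lie strictly inside (0, duration)")
    if any(b <= a for a, b in zip(cps, cps[1:])):
        raise ValueError("changepoints must be strictly increasing")
    bounds = [0.0] + cps + [duration]
    n_seg = len(bounds) - 1
    if speeds_bp_s is None:
        speeds_bp_s = [speed_bp_s] * n_seg
    if len(speeds_bp_s) != n_seg:
        raise ValueError("need one speed per piece")
    rng = rng if rng is not None else rng_for(cfg.seed, "translocation")

    n = int(round(duration / dt))
    t = dt * np.arange(n)
    x0 = cfg.tether_length_um / 2.0 if start is None else float(start)
    x = np.full(n, x0)
    pos = x0
    events = []
    for (a, b), v in zip(zip(bounds, bounds[1:]), speeds_bp_s):
        v_um = direction * v * cfg.um_per_bp
        m = (t >= a) & (t < b) if b < duration else (t >= a)
        x[m] = pos + v_um * (t[m] - a)
        events.append({"kind": "translocation", "t_start": a, "t_end": b,
                       "speed_bp_s": direction * v, "distance_bp": direction * v * (b - a)})
        pos += v_um * (b - a)

    noisy = x + rng.standard_normal(n) * cfg.noise_sigma if cfg.noise_sigma > 0 else x.copy()
    track = Track("transloc_red", "red", t, noisy, source={"synthetic": "translocation"})
    gt = GroundTruth(events=events, params={
        "speed_bp_s": speed_bp_s, "direction": direction, "duration": duration,
        "changepoints": cps, "speeds_bp_s": list(speeds_bp_s)})
    if with_nucleosome:
        nuc = x + rng.standard_normal(n) * cfg.noise_sigma if cfg.noise_sigma > 0 else x.copy()
        nuc_track = Track("transloc_green", "green", t, nuc,
                          source={"synthetic": "translocation"})
        return track, nuc_track, gt
    return track, gt


def simulate_force_clamp_trace(n_nucleosomes: int, cfg: SimulationConfig,
                               step_size_nm: float = 25.0, noise_sigma_nm: float = 2.0,
                               rate: float = 0.5, sample_dt: float = 0.02,
                               baseline_nm: float = 0.0, pad_s: float = 4.0,
                               rng: np.random.Generator | None = None
                               ) -> tuple[ForceTrace, GroundTruth]:
    """Simulate a 15-20 pN force-clamp extension trace with unwrapping steps.

    Each of ``n_nucleosomes`` releases its inner DNA turn as one discrete
    ``step_size_nm`` length increase at an exponential waiting time
    (``rate`` per second), on top of Gaussian distance noise.
    """
    if n_nucleosomes < 0:
        raise ValueError("n_nucleosomes must be >= 0")
    if step_size_nm < 0:
        raise ValueError("step size must be >= 0")
    rng = rng if rng is not None else rng_for(cfg.seed, "force_clamp")
    waits = rng.exponential(1.0 / rate, size=n_nucleosomes) if n_nucleosomes else np.array([])
    step_times = np.sort(pad_s + np.cumsum(waits)) if n_nucleosomes else np.array([])
    duration = (step_times[-1] if n_nucleosomes else 0.0) + pad_s
    t = np.arange(0.0, duration + sample_dt, sample_dt)
    mean = baseline_nm + step_size_nm * np.searchsorted(step_times, t, side="right")
    dist = mean + rng.standard_normal(t.size) * noise_sigma_nm
    trace = ForceTrace(t, dist, force=np.full(t.size, 15.0),
                       clamp_window=(float(t[0]), float(t[-1])))
    gt = GroundTruth(events=[{"kind": "unwrap", "t": float(st), "size_nm": step_size_nm}
                             for st in step_times],
                     params={"n_nucleosomes": n_nucleosomes, "step_size_nm": step_size_nm,
                             "noise_sigma_nm": noise_sigma_nm, "rate": rate})
    return trace, gt


def apply_observation_model(track: Track, cfg: SimulationConfig,
                            rng: np.random.Generator | None = None) -> Track:
    """Apply pulsed-excitation gaps and single-step photobleaching.

    Frames in dark intervals of ``cfg.pulse_pattern`` = (on_s, off_s) are
    marked unobserved; an exponential bleach time (rate ``cfg.bleach_rate``)
    truncates the observed portion of the track.
    """
    rng = rng if rng is not None else rng_for(cfg.seed, "observation")
    mask = track.observed_mask.copy()
    if cfg.pulse_pattern is not None:
        on_s, off_s = cfg.pulse_pattern
        period = on_s + off_s
        phase = np.mod(track.times - track.times[0], period)
        mask &= phase < on_s
    if cfg.bleach_rate > 0:
        t_bleach = track.times[0] + rng.exponential(1.0 / cfg.bleach_rate)
        mask &= track.times <= t_bleach
    out = Track(track.track_id, track.channel, track.times.copy(), track.positions.copy(),
                mask, dict(track.source, observation_model=True))
    return out


def simulate_search_engage_translocate(cfg: SimulationConfig, push: bool = True,
                                       approach_direction: int = 1,
                                       search_s: float = 4.0, engage_s: float = 3.0,
                                       transloc_s: float = 33.0, speed_bp_s: float = 29.0,
                                       approach_speed_um_s: float = 0.35,
                                       search_D: float = 0.01,
                                       rng: np.random.Generator | None = None):
    """Compose a full encounter story: 1D search -> static engagement ->
    processive translocation, with a nucleosome track for colocalization.

    ``push=True`` translocates in the approach direction (NDR-widening,
    RSC-like); ``push=False`` in the opposite direction (NDR-narrowing,
    ISW2-like).  Returns (remodeler_track, nucleosome_track, ground_truth).
    """
    rng = rng if rng is not None else rng_for(cfg.seed, "search_engage")
    dt = cfg.line_time
    n_search = int(round(search_s / dt))
    n_engage = int(round(engage_s / dt))
    n_trans = int(round(transloc_s / dt))
    n = n_search + n_engage + n_trans
    t = dt * np.arange(n)

    nuc0 = cfg.tether_length_um / 2.0
    # biased diffusive approach ending at the nucleosome
    drift = approach_direction * approach_speed_um_s * dt
    steps = drift + rng.standard_normal(n_search) * np.sqrt(2.0 * search_D * dt)
    walk = np.cumsum(steps)
    search = nuc0 + (walk - walk[-1])  # pinned to arrive at the nucleosome

    engage = np.full(n_engage, nuc0)
    v_dir = approach_direction if push else -approach_direction
    v_um = v_dir * speed_bp_s * cfg.um_per_bp
    trans = nuc0 + v_um * dt * np.arange(1, n_trans + 1)

    mean_rem = np.concatenate([search, engage, trans])
    mean_nuc = np.concatenate([np.full(n_search + n_engage, nuc0), trans])
    noise = cfg.noise_sigma if cfg.noise_sigma > 0 else 0.0
    rem = Track("rem", "red", t, mean_rem + rng.standard_normal(n) * noise,
                source={"synthetic": "search_engage_translocate"})
    nuc = Track("nuc", "green", t, mean_nuc + rng.standard_normal(n) * noise,
                source={"synthetic": "search_engage_translocate"})
    gt = GroundTruth(events=[
        {"kind": "search_1D", "t_start": 0.0, "t_end": float(t[n_search - 1])},
        {"kind": "engaged_static", "t_start": float(t[n_search]),
         "t_end": float(t[n_search + n_engage - 1])},
        {"kind": "translocation", "t_start": float(t[n_search + n_engage]),
         "t_end": float(t[-1]), "speed_bp_s": v_dir * speed_bp_s},
    ], params={"push": push, "approach_direction": approach_direction,
               "translocation_direction": v_dir, "speed_bp_s": speed_bp_s})
    return rem, nuc, gt
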