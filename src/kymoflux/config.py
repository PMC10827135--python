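"""Physical constants, instrument parameters and run configuration.

All positions are carried internally in micrometres (um) and times in
seconds; base pairs enter and leave only through the single configured
``um_per_bp`` conversion.  Defaults correspond to a confocal line-scan
instrument with a 42.4 ms line time and ~72 nm (≈225 bp) one-dimensional
localization resolution on lambda DNA held under ~5 pN of tension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

#: seconds per kymograph line (camera exposure / line time)
DEFAULT_LINE_TIME = 0.0424

#: um per kymograph pixel: the instrument's 1D resolution, 72 nm = 225 bp
DEFAULT_PIXEL_TO_UM = 0.072

#: um of tether contour per base pair under ~5 pN tension (72 nm / 225 bp)
DEFAULT_UM_PER_BP = 0.072 / 225.0

#: diffusion-state thresholds in um^2/s: D < 0.01 -> non-diffusive
#: (immobile dCas9 control), 0.01 <= D < 0.04 -> low, D >= 0.04 -> high
D_THRESHOLD_NON = 0.01
D_THRESHOLD_HIGH = 0.04

#: rolling-window MSD parameters (frames / lags)
DEFAULT_WINDOW = 20
DEFAULT_FIT_POINTS = 5
DEFAULT_MIN_RUN = 10

#: colocalization smoothing window and long-event cutoff, in frames
DEFAULT_SMOOTH_SPAN = 5
DEFAULT_LONG_MIN = 5

#: remodeler-nucleosome colocalization radius, base pairs
DEFAULT_NUC_RADIUS_BP = 500.0

#: translocation admission filters
MIN_TRANSLOC_BP = 300.0
MIN_TRANSLOC_S = 5.0
MIN_TRANSLOC_R2 = 0.5

#: nucleosome unwrapping step under a 15-20 pN force clamp, nm
DEFAULT_UNWRAP_STEP_NM = 25.0


@dataclass
class SimulationConfig:
    """Instrument/geometry parameters shared by simulators and analyses.

    Parameters
    ----------
    line_time
        Seconds per frame (kymograph line).
    pixel_to_um
        Micrometres per pixel; "one pixel of localization noise" means a
        Gaussian with this standard deviation.
    um_per_bp
        Tether micrometres per base pair; every bp <-> um conversion in the
        package flows through this one constant.
    tether_length_bp
        Tether length in base pairs (lambda DNA: 48 502 bp).
    noise_sigma
        Localization noise standard deviation per observed frame, um.
    bleach_rate
        Single-step photobleaching rate, 1/s (0 disables bleaching).
    pulse_pattern
        Optional (on_s, off_s) excitation schedule; frames falling in an
        "off" interval are recorded as unobserved.  ``None`` = continuous.
    """

    line_time: float = DEFAULT_LINE_TIME
    pixel_to_um: float = DEFAULT_PIXEL_TO_UM
    um_per_bp: float = DEFAULT_UM_PER_BP
    tether_length_bp: float = 48502.0
    seed: int = 0
    noise_sigma: float = 0.0
    bleach_rate: float = 0.0
    pulse_pattern: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.line_time <= 0:
            raise ValueError("line_time must be > 0")
        if self.um_per_bp <= 0:
            raise ValueError("um_per_bp must be > 0")
        if self.pixel_to_um <= 0:
            raise ValueError("pixel_to_um must be > 0")

    @property
    def tether_length_um(self) -> float:
        return self.tether_length_bp * self.um_per_bp

    def bp_to_um(self, bp):
        return np.asarray(bp, dtype=float) * self.um_per_bp

    def um_to_bp(self, um):
        return np.asarray(um, dtype=float) / self.um_per_bp


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent generator for a named module stream.

    A single user-facing seed fans out to per-module streams through
    ``SeedSequence`` spawn keys, so adding or reordering pipeline stages
    never perturbs the randomness of the others.
    """
    key = int.from_bytes(stream.encode("utf-8"), "little") % (2**31 - 1)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def default_run_config() -> dict:
    """Full parameter block with every analysis default, ready to serialize."""
    return {
        "constants": asdict(SimulationConfig()),
        "diffusion": {
            "window": DEFAULT_WINDOW,
            "fit_points": DEFAULT_FIT_POINTS,
            "thresholds": [D_THRESHOLD_NON, D_THRESHOLD_HIGH],
            "min_run": DEFAULT_MIN_RUN,
            "smooth_span": DEFAULT_SMOOTH_SPAN,
        },
        "dwell": {"components": "auto", "censoring": "none", "min_duration_s": DEFAULT_LINE_TIME},
        "coloc": {
            "threshold": "auto",
            "long_min": DEFAULT_LONG_MIN,
            "smooth_span": DEFAULT_SMOOTH_SPAN,
            "nuc_radius_bp": DEFAULT_NUC_RADIUS_BP,
        },
        "transloc": {
            "min_bp": MIN_TRANSLOC_BP,
            "min_s": MIN_TRANSLOC_S,
            "min_r2": MIN_TRANSLOC_R2,
            "penalty": "auto",
        },
        "force_steps": {"expected_step_nm": DEFAULT_UNWRAP_STEP_NM, "clamp_pN": [15.0, 20.0]},
        "seed": 0,
    }


def load_run_config(path: str | Path) -> dict:
    """Load a YAML/JSON run config, filling unspecified blocks with defaults."""
    cfg = default_run_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, block in user.items():
        if isinstance(block, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(block)
        else:
            cfg[key] = block
    return cfg
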