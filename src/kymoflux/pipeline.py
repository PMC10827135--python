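"""End-to-end orchestration and the synthetic validation suite.

``run_pipeline`` composes the per-module analyses over a set of input
tracks (and optionally a force trace) into a single serializable report;
``run_validation_suite`` executes the parameter-recovery studies that
certify each stage against the synthetic generator's ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as _coloc
from . import diffusion as _diff
from . import dwell as _dwell
from . import force_steps as _force
from . import synthetic as _syn
from . import transloc as _transloc
from .config import SimulationConfig, default_run_config, rng_for
from .tracks import ForceTrace, Track, read_force_trace, read_tracks

log = logging.getLogger("kymoflux")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(tracks: list[Track] | str | Path, config: dict | None = None,
                 force_trace: ForceTrace | str | Path | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run tracks through diffusion, dwell, colocalization and translocation.

    ``tracks`` may be a list of :class:`Track` or a CSV path.  Red-channel
    tracks are treated as remodelers, green-channel tracks as nucleosomes.
    Returns the report dict; with ``out_dir`` set, also persists the report
    JSON and per-stage CSV tables.
    """
    cfg = dict(default_run_config())
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    sim = SimulationConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in cfg["constants"].items()})
    if isinstance(tracks, (str, Path)):
        tracks = read_tracks(tracks, cfg.get("dialect", "native"), sim)
    if isinstance(force_trace, (str, Path)):
        force_trace = read_force_trace(force_trace, tuple(cfg["force_steps"]["clamp_pN"]))

    report: dict = {"n_tracks": len(tracks), "errors": []}
    dc = cfg["diffusion"]

    # stage 1: per-track diffusion profiles; bound lifetimes per channel
    profiles = {}
    diff_rows = []
    for tr in tracks:
        try:
            if len(tr) < dc["window"]:
                continue
            prof = _diff.diffusion_profile(
                tr, dc["window"], dc["fit_points"], tuple(dc["thresholds"]),
                dc["min_run"], dc["smooth_span"])
            profiles[(tr.track_id, tr.channel)] = prof
            row = {"track_id": tr.track_id, "channel": tr.channel,
                   "n_frames": len(tr), "duration_s": tr.duration,
                   "mean_D": float(np.nanmean(prof.D_window))}
            row.update({f"frac_{k}": v for k, v in prof.state_fractions.items()})
            diff_rows.append(row)
        except Exception as exc:  # pragma: no cover - defensive per-stage ledger
            report["errors"].append({"stage": "diffusion", "track": tr.track_id,
                                     "error": str(exc)})
    report["diffusion"] = diff_rows
    log.info("diffusion: %d/%d tracks profiled", len(diff_rows), len(tracks))

    # stage 2: bound-lifetime dwell fits per channel
    samples = {}
    for chan in ("red", "green"):
        durs = [tr.duration for tr in tracks if tr.channel == chan and tr.duration > 0]
        if durs:
            samples[chan] = _dwell.DwellSample(np.array(durs), condition=chan)
    dwell_table = _dwell.bound_lifetime_by_condition(
        samples, cfg["dwell"]["components"], cfg["dwell"]["censoring"]) if samples \
        else pd.DataFrame()
    report["bound_lifetimes"] = dwell_table.to_dict("records")

    # stage 3: remodeler-nucleosome colocalization
    red = [tr for tr in tracks if tr.channel == "red"]
    green = [tr for tr in tracks if tr.channel == "green"]
    cc = cfg["coloc"]
    events_by_track = {}
    if green:
        nuc_map = _coloc.build_nucleosome_map(green)
        for tr in red:
            events_by_track[tr.track_id] = _coloc.remodeler_nucleosome_coloc(
                tr, nuc_map, cfg=sim, radius_bp=cc["nuc_radius_bp"])
    report["nucleosome_coloc"] = [
        {"track_id": tid, "n_events": len(evs),
         "total_coloc_s": float(sum(e.duration for e in evs))}
        for tid, evs in events_by_track.items()]

    # stage 4: translocation segmentation, fragmentation, push-pull
    tc = cfg["transloc"]
    seg_rows, pp_counts = [], {"push": 0, "pull": 0, "undefined": 0}
    for tr in red:
        segs = _transloc.segment_speeds(
            tr, sim, tc["penalty"], tc["min_bp"], tc["min_s"], tc["min_r2"])
        for s in segs:
            seg_rows.append({"track_id": tr.track_id, "t_start": s.t_start,
                             "t_end": s.t_end, "speed_bp_s": s.speed_bp_s,
                             "distance_bp": s.distance_bp, "r2": s.r_squared,
                             "admitted": s.admitted, "reason": s.rejection_reason})
        if any(s.admitted for s in segs):
            prof = profiles.get((tr.track_id, "red"))
            frag = _transloc.fragment_trace(tr, prof,
                                            events_by_track.get(tr.track_id, []), segs)
            call = _transloc.classify_push_pull(tr, frag, segs)
            pp_counts[call.call] += 1
    report["translocation_segments"] = seg_rows
    report["push_pull_counts"] = pp_counts

    # stage 5: nucleosome counting
    if force_trace is not None:
        fs = cfg["force_steps"]
        record = _force.detect_unwrap_steps(force_trace, fs["expected_step_nm"])
        report["nucleosome_count"] = _force.count_nucleosomes(
            record, fs["expected_step_nm"])
        report["unwrap_steps"] = {"times_s": record.step_times,
                                  "sizes_nm": record.step_sizes}

    report = _jsonable(report)
    blob = json.dumps({k: v for k, v in report.items() if k != "provenance"},
                      sort_keys=True)
    report["provenance"] = {
        "seed": cfg.get("seed"),
        "config_hash": hashlib.sha256(json.dumps(_jsonable(cfg), sort_keys=True)
                                      .encode()).hexdigest()[:16],
        "report_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        pd.DataFrame(report["diffusion"]).to_csv(out / "diffusion.csv", index=False)
        pd.DataFrame(seg_rows).to_csv(out / "translocation_segments.csv", index=False)
        dwell_table.to_csv(out / "bound_lifetimes.csv", index=False)
    return report


# --- synthetic validation suite ------------------------------------------------


def _check_diffusion_recovery(seed: int, n_tracks: int, n_frames: int) -> dict:
    cfg = SimulationConfig(seed=seed)
    expected = {0.005: "non", 0.02: "low", 0.05: "high"}
    accs = {}
    rng = rng_for(seed, "validate_diffusion")
    for D, want in expected.items():
        hits = 0
        for _ in range(n_tracks):
            model = _syn.DiffusionStateModel.single_state(D)
            tr, _ = _syn.simulate_switching_track(model, cfg, n_frames * cfg.line_time,
                                                  rng=rng)
            Dw = _diff.rolling_window_D(tr)
            labels = _diff.classify_windows(Dw)
            vals, counts = np.unique(labels, return_counts=True)
            if vals[np.argmax(counts)] == want:
                hits += 1
        accs[D] = hits / n_tracks
    return {"name": "diffusion_state_recovery", "detail": accs,
            "passed": all(a >= 0.9 for a in accs.values())}


def _check_dwell_recovery(seed: int, n: int) -> dict:
    ok = True
    detail = {}
    rng = rng_for(seed, "validate_dwell")
    for tau in (0.03, 0.7, 3.8, 12.0, 18.0, 28.0):
        d = _syn.simulate_dwells(n, [tau], rng=rng)
        fit = _dwell.fit_exponential(_dwell.DwellSample(d), 1)
        bias = abs(fit.taus[0] - tau) / tau
        detail[tau] = bias
        ok &= bias < 0.05 or abs(fit.taus[0] - tau) < 3 * tau / np.sqrt(n)
    return {"name": "dwell_tau_recovery", "detail": detail, "passed": bool(ok)}


def _check_translocation_recovery(seed: int, n_traces: int) -> dict:
    cfg = SimulationConfig(seed=seed, noise_sigma=0.072)
    rng = rng_for(seed, "validate_transloc")
    speeds = []
    for _ in range(n_traces):
        tr, _ = _syn.simulate_translocation_track(29.0, 33.0, cfg, rng=rng)
        segs = [s for s in _transloc.segment_speeds(tr, cfg) if s.admitted]
        speeds.extend(s.speed_bp_s for s in segs)
    mean_speed = float(np.mean(speeds)) if speeds else np.nan
    passed = bool(speeds) and abs(mean_speed - 29.0) / 29.0 < 0.05
    return {"name": "translocation_speed_recovery",
            "detail": {"mean_speed_bp_s": mean_speed, "n_segments": len(speeds)},
            "passed": passed}


def _check_force_recovery(seed: int, n_runs: int) -> dict:
    cfg = SimulationConfig(seed=seed)
    rng = rng_for(seed, "validate_force")
    detail = {}
    ok = True
    for n_nuc in (10, 30):
        hits = 0
        for _ in range(n_runs):
            trace, _ = _syn.simulate_force_clamp_trace(n_nuc, cfg, rng=rng)
            rec = _force.detect_unwrap_steps(trace)
            if _force.count_nucleosomes(rec) == n_nuc:
                hits += 1
        detail[n_nuc] = hits / n_runs
        ok &= detail[n_nuc] >= 0.95
    return {"name": "nucleosome_count_recovery", "detail": detail, "passed": bool(ok)}


def run_validation_suite(seed: int = 0, scale: float = 1.0) -> pd.DataFrame:
    """Execute the parameter-recovery studies for every stage.

    ``scale`` shrinks the study sizes for a fast run (e.g. 0.2); the full
    sizes are 50 tracks x 5000 frames (diffusion), n=1000 dwells, 100
    translocation traces, 100 force-clamp runs per array size.
    """
    checks = [
        _check_diffusion_recovery(seed, max(5, int(50 * scale)), 5000),
        _check_dwell_recovery(seed, max(200, int(1000 * scale))),
        _check_translocation_recovery(seed, max(10, int(100 * scale))),
        _check_force_recovery(seed, max(10, int(100 * scale))),
    ]
    return pd.DataFrame([{"check": c["name"], "passed": c["passed"],
                          "detail": json.dumps(_jsonable(c["detail"]))}
                         for c in checks])
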