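"""Translocation segmentation, admission filters, fragmentation, push/pull."""

import numpy as np
import pytest

from kymoflux import (SimulationConfig, Track, classify_push_pull,
                      detect_direction_changes, fragment_trace, segment_speeds,
                      simulate_search_engage_translocate,
                      simulate_translocation_track)
from kymoflux.config import rng_for
from kymoflux.coloc import EncounterEvent
from kymoflux.transloc import TranslocationSegment

DT = 0.0424


@pytest.fixture
def noisy_cfg():
    return SimulationConfig(seed=31, noise_sigma=0.072)  # one pixel of noise


class TestSegmentSpeeds:
    def test_noiseless_29bps_trace_admitted_with_exact_speed(self, cfg):
        tr, _ = simulate_translocation_track(29.0, 33.0, cfg)
        segs = segment_speeds(tr, cfg)
        adm = [s for s in segs if s.admitted]
        assert len(adm) == 1
        assert abs(adm[0].speed_bp_s - 29.0) < 0.5
        assert abs(adm[0].distance_bp - 957.0) < 30.0
        assert adm[0].r_squared > 0.99

    def test_short_distance_rejected_with_reason(self, cfg):
        tr, _ = simulate_translocation_track(20.0, 10.0, cfg)  # 200 bp in 10 s
        segs = segment_speeds(tr, cfg)
        assert not any(s.admitted for s in segs)
        assert any("distance<300bp" in s.rejection_reason for s in segs)

    def test_two_speed_trace_recovers_both_speeds(self, noisy_cfg):
        # 40 s per piece: a 20 bp/s segment needs ~40 s at one pixel of
        # noise before its R^2 clears the 0.5 admission filter
        tr, _ = simulate_translocation_track(
            0.0, 80.0, noisy_cfg, changepoints=[40.0], speeds_bp_s=[20.0, 40.0],
            rng=rng_for(32, "twospeed"))
        adm = [s for s in segment_speeds(tr, noisy_cfg) if s.admitted]
        assert len(adm) == 2
        assert abs(adm[0].speed_bp_s - 20.0) / 20.0 < 0.10
        assert abs(adm[1].speed_bp_s - 40.0) / 40.0 < 0.10

    @pytest.mark.parametrize("speed,duration", [(10.0, 100.0), (29.0, 40.0),
                                                (60.0, 20.0)])
    def test_speed_recovery_sweep_with_noise(self, noisy_cfg, speed, duration):
        # slower events need longer traces to clear the R^2 >= 0.5 filter at
        # one pixel of localization noise, as the published detection regime
        rng = rng_for(33, f"sweep{speed}")
        got = []
        for _ in range(20):
            tr, _ = simulate_translocation_track(speed, duration, noisy_cfg,
                                                 rng=rng)
            got.extend(s.speed_bp_s for s in segment_speeds(tr, noisy_cfg)
                       if s.admitted)
        assert got, f"no admitted segments at {speed} bp/s"
        assert abs(np.mean(got) - speed) / speed < 0.05

    def test_static_control_traces_yield_nothing(self, noisy_cfg):
        rng = rng_for(34, "static")
        for _ in range(20):
            tr, _ = simulate_translocation_track(0.0, 33.0, noisy_cfg, rng=rng)
            assert not any(s.admitted for s in segment_speeds(tr, noisy_cfg))

    def test_distance_equals_speed_times_duration(self, noisy_cfg):
        tr, _ = simulate_translocation_track(29.0, 33.0, noisy_cfg,
                                             rng=rng_for(35, "cons"))
        for s in segment_speeds(tr, noisy_cfg):
            if s.admitted:
                assert np.isclose(s.distance_bp, s.speed_bp_s * s.duration,
                                  rtol=1e-9)

    def test_manual_changepoints_path(self, cfg):
        tr, _ = simulate_translocation_track(0.0, 20.0, cfg, changepoints=[10.0],
                                             speeds_bp_s=[20.0, 40.0])
        segs = segment_speeds(tr, cfg, manual_changepoints=[10.0])
        assert len(segs) == 2
        assert abs(segs[1].speed_bp_s - 40.0) < 1.0

    def test_too_short_track_empty(self, cfg):
        tr, _ = simulate_translocation_track(29.0, 2.0, cfg)
        assert segment_speeds(tr, cfg) == []


class TestDirectionChanges:
    def _seg(self, speed, t0=0.0):
        return TranslocationSegment(t0, t0 + 10, speed, speed * 10, 0.9, True)

    def test_sign_flip_counted(self):
        n, _ = detect_direction_changes([self._seg(29), self._seg(-29, 10)])
        assert n == 1

    def test_single_segment_no_changes(self):
        assert detect_direction_changes([self._seg(29)])[0] == 0

    def test_speed_change_same_sign_not_counted(self):
        assert detect_direction_changes([self._seg(20), self._seg(40, 10)])[0] == 0


class TestFragmentation:
    def test_pure_diffusion_all_search(self, cfg):
        t = DT * np.arange(100)
        tr = Track("r", "red", t, np.cumsum(np.full(100, 0.01)))
        frag = fragment_trace(tr, None, [], [])
        assert set(frag.labels) == {"search_1D"}

    def test_parked_track_all_engaged(self, cfg):
        t = DT * np.arange(100)
        tr = Track("r", "red", t, np.full(100, 2.0))
        ev = EncounterEvent("nucleosome_coloc", 0.0, t[-1], t[-1] + DT, 0.0,
                            ("r", "n"))
        frag = fragment_trace(tr, None, [ev], [])
        assert set(frag.labels) == {"engaged_static"}

    def test_three_phase_trace_ordered_segments(self, noisy_cfg):
        from kymoflux import build_nucleosome_map, remodeler_nucleosome_coloc
        rem, nuc, _ = simulate_search_engage_translocate(
            noisy_cfg, push=True, rng=rng_for(36, "threephase"))
        nmap = build_nucleosome_map([nuc], stability_sd_um=1e9)
        evs = remodeler_nucleosome_coloc(rem, nmap, cfg=noisy_cfg)
        segs = segment_speeds(rem, noisy_cfg)
        frag = fragment_trace(rem, None, evs, segs)
        labels = [s[0] for s in frag.segments]
        assert labels[0] == "search_1D"
        assert labels[-1] == "translocating"


class TestPushPull:
    def _run(self, cfg, push, adir, rng):
        from kymoflux import build_nucleosome_map, remodeler_nucleosome_coloc
        rem, nuc, _ = simulate_search_engage_translocate(
            cfg, push=push, approach_direction=adir, rng=rng)
        nmap = build_nucleosome_map([nuc], stability_sd_um=1e9)
        evs = remodeler_nucleosome_coloc(rem, nmap, cfg=cfg)
        segs = segment_speeds(rem, cfg)
        frag = fragment_trace(rem, None, evs, segs)
        return classify_push_pull(rem, frag, segs)

    def test_same_direction_is_push(self, noisy_cfg):
        call = self._run(noisy_cfg, True, 1, rng_for(37, "push"))
        assert call.call == "push"
        assert call.approach_direction == call.translocation_direction

    def test_opposite_direction_is_pull(self, noisy_cfg):
        call = self._run(noisy_cfg, False, 1, rng_for(38, "pull"))
        assert call.call == "pull"

    def test_no_search_segment_undefined(self, cfg):
        tr, _ = simulate_translocation_track(29.0, 33.0, cfg)
        segs = segment_speeds(tr, cfg)
        frag = fragment_trace(tr, None, [], segs)
        call = classify_push_pull(tr, frag, segs)
        assert call.call == "undefined"
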