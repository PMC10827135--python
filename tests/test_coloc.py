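"""Two-color colocalization detection, classification and nucleosome maps."""

import numpy as np
import pytest

from kymoflux import (SimulationConfig, Track, build_nucleosome_map, classify_encounter,
                      classify_encounters, colocalization_threshold, detect_bypass,
                      detect_colocalized_frames, event_proportions,
                      remodeler_nucleosome_coloc, simulate_encounter_pair)
from kymoflux.config import rng_for

DT = 0.0424


def _lin(tid, x0, v, n=40, channel="red"):
    t = DT * np.arange(n)
    return Track(tid, channel, t, x0 + v * t)


class TestThreshold:
    def test_zero_diffusion_zero_threshold(self):
        assert colocalization_threshold(0.0, 0.0, DT).d_threshold == 0.0

    def test_closed_form_value(self):
        thr = colocalization_threshold(0.04, 0.04, DT)
        assert np.isclose(thr.d_threshold, 2 * np.sqrt(2 * 0.04 * DT), rtol=1e-12)
        assert np.isclose(thr.d_threshold, 0.11648, atol=5e-5)

    def test_monotone_in_each_D(self, rng):
        for _ in range(20):
            D1, D2, dt = rng.uniform(0.001, 0.2, 3)
            base = colocalization_threshold(D1, D2, dt).d_threshold
            assert colocalization_threshold(D1 * 2, D2, dt).d_threshold > base
            assert colocalization_threshold(D1, D2 * 2, dt).d_threshold > base
            # independent numeric check of the closed form
            assert np.isclose(base, np.sqrt(2 * D1 * dt) + np.sqrt(2 * D2 * dt))

    def test_fixed_threshold_override(self):
        thr = colocalization_threshold(0.04, 0.04, DT, fixed_threshold=0.31)
        assert np.isclose(thr.d_threshold, 0.31)
        assert np.isclose(thr.x1 + thr.x2, 0.31)


class TestDetection:
    def test_parallel_distant_tracks_no_intervals(self):
        thr = colocalization_threshold(0.04, 0.04, DT)
        assert detect_colocalized_frames(_lin("a", 0.0, 0.0), _lin("b", 1.0, 0.0),
                                         thr) == []

    def test_identical_tracks_one_full_interval(self):
        thr = colocalization_threshold(0.04, 0.04, DT)
        ivs = detect_colocalized_frames(_lin("a", 1.0, 0.1, n=20),
                                        _lin("b", 1.0, 0.1, n=20), thr)
        assert ivs == [(0, 20)]

    def test_crossing_tracks_single_interval_at_crossing(self):
        thr = colocalization_threshold(0.04, 0.04, DT)
        a = _lin("a", 0.0, 0.5, n=60)
        b = _lin("b", 1.2718, -0.5, n=60)  # cross mid-trace
        ivs = detect_colocalized_frames(a, b, thr)
        assert len(ivs) == 1
        lo, hi = ivs[0]
        assert lo < 30 < hi

    def test_symmetry_in_track_order(self, cfg):
        rng = rng_for(21, "sym")
        t1, t2, _ = simulate_encounter_pair(cfg, "codiffuse", {"dwell_mean": 0.5},
                                            rng=rng)
        thr = colocalization_threshold(0.04, 0.04, DT)
        assert detect_colocalized_frames(t1, t2, thr) == \
            detect_colocalized_frames(t2, t1, thr)

    def test_no_temporal_overlap_empty(self):
        a = _lin("a", 0.0, 0.0, n=10)
        b = Track("b", "green", 100 + DT * np.arange(10), np.zeros(10))
        thr = colocalization_threshold(0.04, 0.04, DT)
        assert detect_colocalized_frames(a, b, thr) == []


class TestClassification:
    def test_twenty_frame_interval_auto_long(self):
        thr = colocalization_threshold(0.04, 0.04, DT)
        a, b = _lin("a", 1.0, 0.1, n=30), _lin("b", 1.0, 0.1, n=30)
        ev = classify_encounter((0, 20), a, b, thr)
        assert ev.kind == "long_coloc"

    def test_fast_graze_is_short(self):
        # 2-frame brush with large pre/post separation changes
        thr = colocalization_threshold(0.04, 0.04, DT)
        sep = np.array([0.9, 0.6, 0.3, 0.05, 0.05, 0.3, 0.6, 0.9])
        a = Track("a", "red", DT * np.arange(8), np.zeros(8))
        b = Track("b", "green", DT * np.arange(8), sep)
        ev = classify_encounter((3, 5), a, b, thr)
        assert ev.kind == "short_coloc"

    def test_static_brief_interval_is_long(self):
        thr = colocalization_threshold(0.04, 0.04, DT)
        sep = np.full(12, 0.05)
        a = Track("a", "red", DT * np.arange(12), np.zeros(12))
        b = Track("b", "green", DT * np.arange(12), sep)
        ev = classify_encounter((4, 6), a, b, thr)
        assert ev.kind == "long_coloc"

    def test_event_mix_recovery_short_vs_long(self, cfg):
        thr = colocalization_threshold(0.04, 0.04, DT)
        rng = rng_for(22, "mix")
        correct = {"recoil": [0, 0], "codiffuse": [0, 0]}
        want = {"recoil": "short_coloc", "codiffuse": "long_coloc"}
        for scen, dwell_mean in (("recoil", 0.033), ("codiffuse", 0.70)):
            for _ in range(200):
                t1, t2, gt = simulate_encounter_pair(
                    cfg, scen, {"dwell_mean": dwell_mean, "D": 0.04}, rng=rng)
                ev0 = gt.events[0]
                evs = [e for e in classify_encounters(t1, t2, thr)
                       if e.t_end >= ev0["t_start"] and e.t_start <= ev0["t_end"]]
                if not evs:
                    continue
                ev = max(evs, key=lambda e: e.duration)
                correct[scen][1] += 1
                correct[scen][0] += ev.kind == want[scen]
        for scen, (ok, n) in correct.items():
            assert n > 50, f"{scen}: too few detected events"
            assert ok / n >= 0.9, f"{scen}: accuracy {ok / n:.2f}"


class TestBypass:
    def _crossing_pair(self, n=60):
        return _lin("a", 0.0, 0.5, n=n), _lin("b", 1.2718, -0.5, n=n)

    def test_crossing_is_bypass(self):
        thr = colocalization_threshold(0.04, 0.04, DT)
        a, b = self._crossing_pair()
        ivs = detect_colocalized_frames(a, b, thr)
        assert detect_bypass(a, b, ivs) == ivs
        evs = classify_encounters(a, b, thr)
        assert any(e.kind == "bypass" for e in evs)

    def test_recoil_geometry_not_bypass(self):
        thr = colocalization_threshold(0.04, 0.04, DT)
        t = DT * np.arange(60)
        apex = 0.5 * (DT * 30)
        a = Track("a", "red", t, np.zeros(60))
        b = Track("b", "green", t, np.abs(0.5 * t - apex) + 0.01)
        ivs = detect_colocalized_frames(a, b, thr)
        assert detect_bypass(a, b, ivs) == []

    def test_insufficient_flank_not_bypass(self):
        thr = colocalization_threshold(0.04, 0.04, DT)
        a, b = self._crossing_pair()
        ivs = detect_colocalized_frames(a, b, thr)
        lo, hi = ivs[0]
        # truncate both tracks 2 frames after the interval ends
        n_keep = hi + 2
        a2 = Track("a", "red", a.times[:n_keep], a.positions[:n_keep])
        b2 = Track("b", "green", b.times[:n_keep], b.positions[:n_keep])
        ivs2 = detect_colocalized_frames(a2, b2, thr)
        assert detect_bypass(a2, b2, ivs2) == []


class TestNucleosomeMap:
    def test_pulsed_signal_extended_across_dark_gaps(self):
        n = 200
        obs = np.zeros(n, bool)
        obs[:20] = True  # 1 s visible out of ~8.5 s
        tr = Track("nuc1", "green", DT * np.arange(n), np.full(n, 3.0), obs)
        m = build_nucleosome_map([tr])
        t_query = DT * np.arange(n)
        np.testing.assert_allclose(m.position_at("nuc1", t_query), 3.0)

    def test_jittering_signal_excluded(self, rng):
        x = 3.0 + rng.normal(0, 0.5, 100)  # SD >> stability bound
        tr = Track("bad", "green", DT * np.arange(100), x)
        m = build_nucleosome_map([tr], stability_sd_um=0.144)
        assert m.stable_ids == []

    def test_exclusion_propagates_through_links(self, rng):
        good = Track("good", "green", DT * np.arange(50), np.full(50, 2.0))
        bad = Track("bad", "green", 10 + DT * np.arange(50),
                    2.0 + rng.normal(0, 0.5, 50))
        m = build_nucleosome_map([good, bad], stability_sd_um=0.144,
                                 links=[("good", "bad")])
        assert m.stable_ids == []

    def test_no_stable_signals_warns(self, rng):
        bad = Track("bad", "green", DT * np.arange(50), rng.normal(0, 1, 50))
        with pytest.warns(UserWarning, match="no stable"):
            build_nucleosome_map([bad], stability_sd_um=0.01)


class TestRemodelerNucleosome:
    def test_parked_remodeler_single_spanning_event(self, cfg):
        n = 100
        nuc = Track("n", "green", DT * np.arange(n), np.full(n, 2.0))
        rem = Track("r", "red", DT * np.arange(n), np.full(n, 2.05))
        m = build_nucleosome_map([nuc])
        evs = remodeler_nucleosome_coloc(rem, m, cfg=cfg)
        assert len(evs) == 1
        assert np.isclose(evs[0].duration, n * DT, atol=DT)

    def test_distant_remodeler_no_events(self, cfg):
        n = 100
        nuc = Track("n", "green", DT * np.arange(n), np.full(n, 2.0))
        rem = Track("r", "red", DT * np.arange(n),
                    np.full(n, 2.0 + 2000 * cfg.um_per_bp))
        evs = remodeler_nucleosome_coloc(rem, build_nucleosome_map([nuc]), cfg=cfg)
        assert evs == []

    def test_single_frame_crossing_gives_one_frame_event(self, cfg):
        n = 41
        nuc = Track("n", "green", DT * np.arange(n), np.full(n, 2.0))
        x = 2.0 + 0.5 * (np.arange(n) - 20)  # 0.5 um/frame: in radius 1 frame
        rem = Track("r", "red", DT * np.arange(n), x)
        evs = remodeler_nucleosome_coloc(rem, build_nucleosome_map([nuc]), cfg=cfg)
        assert len(evs) == 1
        assert np.isclose(evs[0].duration, DT)


def test_event_proportions_sum_to_one(cfg):
    rng = rng_for(23, "prop")
    thr = colocalization_threshold(0.04, 0.04, DT)
    events = []
    for scen in ("recoil", "codiffuse", "bypass"):
        for _ in range(10):
            t1, t2, _ = simulate_encounter_pair(cfg, scen, {"dwell_mean": 0.2},
                                                rng=rng)
            events.extend(classify_encounters(t1, t2, thr))
    props = event_proportions(events)
    assert np.isclose(sum(props.values()), 1.0)
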