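"""Growth-cone domains, filopodia detection/dynamics, ROI intensities."""

import numpy as np
import pytest

from axonquant import (
    FilopodiumTrace,
    GrowthConeFrame,
    classify_dynamics,
    detect_filopodia,
    partition_domains,
    roi_intensity,
    tip_accumulation,
)
from axonquant.synthetic import make_gc_mask, make_gc_sequence


class TestPartitionDomains:
    def test_circle_erosion_closed_form(self, circle_outline):
        central, peripheral = partition_domains(
            GrowthConeFrame(0.0, circle_outline), "auto", erosion_um=3.0
        )
        assert central.area == pytest.approx(np.pi * 4, rel=0.05)

    def test_manual_polygon_returned_unchanged(self, circle_outline):
        inner = 0.3 * circle_outline
        frame = GrowthConeFrame(0.0, circle_outline, central_domain=inner)
        central, _ = partition_domains(frame, "manual")
        assert central.equals_exact(
            __import__("shapely.geometry", fromlist=["Polygon"]).Polygon(inner), 1e-9
        )

    def test_peripheral_is_exact_area_difference(self):
        # star-shaped outline
        th = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        r = np.where(np.arange(10) % 2 == 0, 6.0, 3.5)
        star = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        from shapely.geometry import Polygon

        central, peripheral = partition_domains(GrowthConeFrame(0.0, star), "auto", 1.0)
        assert peripheral.area == pytest.approx(Polygon(star).area - central.area)

    def test_over_erosion_suggests_smaller_value(self, circle_outline):
        with pytest.raises(ValueError, match="smaller erosion"):
            partition_domains(GrowthConeFrame(0.0, circle_outline), "auto", erosion_um=6.0)


class TestDetectFilopodia:
    def test_smooth_ellipse_has_none(self):
        mask, truth = make_gc_mask([], seed=0)
        assert detect_filopodia(mask, truth["pixel_size"]) == []

    def test_threshold_inclusive_at_two_um(self):
        short, t1 = make_gc_mask([1.9], angles=[0.0])
        ok, t2 = make_gc_mask([2.0], angles=[0.0])
        assert detect_filopodia(short, t1["pixel_size"]) == []
        assert len(detect_filopodia(ok, t2["pixel_size"])) == 1

    def test_programmed_spike_set(self):
        mask, truth = make_gc_mask([0.8, 1.5, 2.0, 2.5, 3.0], seed=1)
        found = sorted(f["length_um"] for f in detect_filopodia(mask, truth["pixel_size"]))
        assert len(found) == 3
        for got, exp in zip(found, [2.0, 2.5, 3.0]):
            assert got == pytest.approx(exp, abs=0.2)

    def test_count_monotone_in_threshold(self):
        mask, truth = make_gc_mask([2.2, 2.8, 3.4, 4.0], seed=2)
        counts = [
            len(detect_filopodia(mask, truth["pixel_size"], min_length_um=thr))
            for thr in [1.0, 2.0, 2.5, 3.0, 3.7, 5.0]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_counts_match_programmed_spikes_over_seeds(self):
        # spike lengths keep a 0.2 um margin from the 2 um decision boundary
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = rng.integers(2, 6)
            lengths = np.where(
                rng.random(n) < 0.4, rng.uniform(0.5, 1.8, n), rng.uniform(2.2, 4.5, n)
            )
            mask, truth = make_gc_mask(list(lengths), seed=seed)
            found = detect_filopodia(mask, truth["pixel_size"])
            assert len(found) == np.sum(lengths >= 2.0), f"seed {seed}"

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_filopodia(np.zeros((10, 10), bool), 0.1)


class TestClassifyDynamics:
    def test_always_present_is_stable_full_lifetime(self):
        s = classify_dynamics([FilopodiumTrace("a", np.full(60, 3.0))])
        assert (s.n_stable, s.n_formation, s.n_retraction) == (1, 0, 0)
        assert s.lifetimes == [300.0]

    def test_late_formation_lifetime(self):
        L = np.zeros(60)
        L[12:] = 3.0
        s = classify_dynamics([FilopodiumTrace("a", L)])
        assert s.n_formation == 1 and s.n_retraction == 0
        assert s.lifetimes == [240.0]

    def test_rise_and_collapse_speed_and_retraction(self):
        L = np.zeros(60)
        L[0:5] = [2, 3, 4, 5, 6]  # 2 -> 6 um over 20 s
        s = classify_dynamics([FilopodiumTrace("a", L)])
        assert s.elongation_speeds == [pytest.approx(0.2)]
        assert s.n_retraction == 1

    def test_fixture_event_counts_match_truth(self):
        _, traces, log = make_gc_sequence(seed=5)
        s = classify_dynamics(traces)
        assert s.n_formation == log["n_formation"]
        assert s.n_retraction == log["n_retraction"]
        assert s.n_stable == log["n_stable"]
        assert s.lifetimes == log["lifetimes"]

    def test_scripted_growth_speed_recovered(self):
        schedule = [
            {"kind": "formation", "t_start": 50.0, "rate": 0.2, "max_length": 4.0}
        ]
        _, traces, _ = make_gc_sequence(event_schedule=schedule, seed=0)
        s = classify_dynamics(traces)
        assert s.elongation_speeds == [pytest.approx(0.2, abs=0.02)]

    def test_order_invariance(self):
        _, traces, _ = make_gc_sequence(seed=9)
        a = classify_dynamics(traces)
        b = classify_dynamics(traces[::-1])
        assert (a.n_formation, a.n_retraction, a.n_stable) == (
            b.n_formation,
            b.n_retraction,
            b.n_stable,
        )
        assert sorted(a.lifetimes) == sorted(b.lifetimes)

    def test_missing_frames_rejected(self):
        L = np.full(60, 3.0)
        L[10] = np.nan
        with pytest.raises(ValueError, match="missing"):
            classify_dynamics([FilopodiumTrace("a", L)])

    def test_off_interval_sampling_warns(self):
        with pytest.warns(UserWarning, match="frame interval"):
            classify_dynamics([FilopodiumTrace("a", np.full(60, 3.0), frame_interval=7.0)])


class TestRoiIntensity:
    def test_forced_arithmetic(self):
        img = np.zeros((40, 40))
        img[0:10, 0:10] = 50.0
        img[0:10, 20:30] = 10.0
        reg = np.array([[0, 0], [0, 9], [9, 9], [9, 0]], float)
        bg = reg + [0, 20]
        r = roi_intensity(img, 1.0, reg, bg)
        assert r.mean_intensity == pytest.approx(40.0)

    def test_identical_statistics_give_zero(self):
        img = np.full((40, 40), 13.0)
        reg = np.array([[0, 0], [0, 9], [9, 9], [9, 0]], float)
        r = roi_intensity(img, 1.0, reg, reg + [0, 20])
        assert r.mean_intensity == 0.0

    def test_recovers_programmed_offset_under_noise(self, rng):
        img = rng.normal(20, 5, (100, 100)).clip(0)
        img[10:40, 10:40] += 25.0
        reg = np.array([[10, 10], [10, 39], [39, 39], [39, 10]], float)
        r = roi_intensity(img, 1.0, reg, reg + [0, 45])
        assert r.mean_intensity == pytest.approx(25.0, abs=2.0)

    def test_overlapping_rois_rejected(self):
        img = np.zeros((40, 40))
        reg = np.array([[0, 0], [0, 9], [9, 9], [9, 0]], float)
        with pytest.raises(ValueError, match="overlap"):
            roi_intensity(img, 1.0, reg, reg + [0, 5])


class TestTipAccumulation:
    def _trace(self, marker_shape=(100, 100)):
        # straight 5-um filopodium along image columns, pixel 0.1 um
        skel = np.stack([np.full(50, 5.0), np.linspace(4.0, 9.0, 50)], axis=1)
        return FilopodiumTrace("f", np.array([5.0]), skeletons=[skel])

    def test_uniform_marker_not_enriched(self):
        enriched, _ = tip_accumulation(self._trace(), np.full((100, 100), 10.0), 0.1)
        assert not enriched

    def test_programmed_ratio_two_is_enriched(self):
        marker = np.full((100, 100), 10.0)
        marker[:, 80:] = 20.0  # distal 1 um at 2x
        enriched, _ = tip_accumulation(self._trace(), marker, 0.1)
        assert enriched

    def test_programmed_ratio_below_factor_not_enriched(self):
        marker = np.full((100, 100), 10.0)
        marker[:, 80:] = 12.0  # 1.2x < 1.5x factor
        enriched, _ = tip_accumulation(self._trace(), marker, 0.1)
        assert not enriched

    def test_filopodium_shorter_than_tip_roi_rejected(self):
        skel = np.stack([np.full(5, 5.0), np.linspace(5.0, 5.5, 5)], axis=1)
        trace = FilopodiumTrace("f", np.array([5.0]), skeletons=[skel])
        with pytest.raises(ValueError, match="tip ROI"):
            tip_accumulation(trace, np.zeros((100, 100)), 0.1)
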