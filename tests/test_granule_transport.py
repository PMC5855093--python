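"""Granule motion classification, fractions, domain distribution, flux."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axonquant import (
    DomainCounts,
    MotionClass,
    Track,
    anterograde_flux,
    classify_motion,
    domain_distribution,
    motion_fractions,
)
from axonquant.granule_transport import pooled_domain_fractions
from axonquant.synthetic import make_domain_timecourse, make_track_fixture

T = np.arange(61.0)


class TestClassifyMotion:
    def test_constant_position_is_static(self):
        assert classify_motion(Track("a", T, np.full(61, 4.0))) is MotionClass.STATIC_OSCILLATORY

    @pytest.mark.parametrize(
        "sign,expected",
        [(+1, MotionClass.ANTEROGRADE), (-1, MotionClass.RETROGRADE)],
    )
    def test_linear_drift_sign_symmetry(self, sign, expected):
        assert classify_motion(Track("a", T, sign * 0.05 * T)) is expected

    def test_excursion_exactly_at_threshold_is_static(self):
        pos = np.zeros(61)
        pos[30] = 2.0
        assert classify_motion(Track("a", T, pos)) is MotionClass.STATIC_OSCILLATORY
        pos[30] = 2.0 + 1e-9
        assert classify_motion(Track("a", T, pos)) is MotionClass.ANTEROGRADE

    def test_fixture_classes_match_generator_labels(self):
        tracks, labels = make_track_fixture("fig6b", seed=7)
        assert [classify_motion(t) for t in tracks] == labels

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            Track("a", [0.0, 2.0, 1.0], [0, 0, 0])

    @given(shift=st.floats(-100, 100))
    @settings(max_examples=30, deadline=None)
    def test_translation_invariance_and_negation_flip(self, shift):
        pos = np.concatenate([np.linspace(0, 3, 31), np.full(30, 3.0)])
        base = classify_motion(Track("a", T, pos))
        assert classify_motion(Track("a", T, pos + shift)) is base
        flipped = classify_motion(Track("a", T, -pos))
        assert (base, flipped) == (MotionClass.ANTEROGRADE, MotionClass.RETROGRADE)


class TestMotionFractions:
    def test_single_track(self):
        fr = motion_fractions([Track("a", T, 0.06 * T)])
        assert fr[MotionClass.ANTEROGRADE] == 100.0
        assert fr[MotionClass.RETROGRADE] == 0.0

    def test_even_split(self):
        tracks = [Track(str(i), T, s * 0.06 * T) for i, s in enumerate([1, 1, -1, -1])]
        fr = motion_fractions(tracks)
        assert fr[MotionClass.ANTEROGRADE] == fr[MotionClass.RETROGRADE] == 50.0

    def test_fig6b_fixture_percentages(self):
        tracks, _ = make_track_fixture("fig6b", seed=7)
        fr = motion_fractions(tracks)
        assert fr[MotionClass.STATIC_OSCILLATORY] == 54.72
        assert fr[MotionClass.RETROGRADE] == 24.53
        assert fr[MotionClass.ANTEROGRADE] == 20.75

    def test_percentages_sum_to_100_before_rounding(self):
        tracks, _ = make_track_fixture("fig6b", seed=3)
        raw = motion_fractions(tracks, ndigits=10)
        assert sum(raw.values()) == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            motion_fractions([])

    def test_bulk_accuracy_on_separated_kinematics(self):
        """Confined sigma keeps excursions < 2 um; drift reaches 3 um."""
        tracks, labels = [], []
        for seed in range(10):
            t1, l1 = make_track_fixture("custom", n=50, drift=0.0, seed=seed)
            t2, l2 = make_track_fixture("custom", n=25, drift=0.05, seed=seed + 100)
            t3, l3 = make_track_fixture("custom", n=25, drift=-0.05, seed=seed + 200)
            tracks += t1 + t2 + t3
            labels += l1 + l2 + l3
        assert len(tracks) == 1000
        pred = [classify_motion(t) for t in tracks]
        assert pred == labels


class TestDomainDistribution:
    def test_all_central_bin(self):
        df = domain_distribution([DomainCounts(0.0, 10, 0)])
        assert df.frac_peripheral.iloc[0] == 0.0

    def test_published_baseline_counts(self):
        df = domain_distribution([DomainCounts(0.0, 382, 118)])
        assert df.frac_central.iloc[0] == pytest.approx(0.764)
        assert df.frac_peripheral.iloc[0] == pytest.approx(0.236)

    def test_fractions_sum_to_one_per_bin(self):
        counts, _ = make_domain_timecourse("heterotypic", seed=3)
        df = domain_distribution(counts)
        assert np.allclose(df.frac_central + df.frac_peripheral, 1.0)

    def test_empty_bin_flagged_not_imputed(self):
        df = domain_distribution([DomainCounts(0.0, 0, 0), DomainCounts(30.0, 3, 1)])
        assert not df.defined.iloc[0] and np.isnan(df.frac_central.iloc[0])
        assert df.defined.iloc[1]

    def test_heterotypic_fixture_elevated_after_contact(self):
        counts, truth = make_domain_timecourse("heterotypic", seed=3)
        df = domain_distribution(counts)
        base = 0.236
        for row, tr in zip(df.itertuples(), truth):
            assert row.time_bin == tr["time_bin"]
            expected = tr["occupancy_peripheral"]
            assert row.frac_peripheral == pytest.approx(expected, abs=0.03)
            if row.time_bin >= 120:
                assert row.frac_peripheral > base + 0.05
        # sustained through the 10-min window
        late = df[df.time_bin >= 210]
        assert (late.frac_peripheral > 0.4).all()

    def test_homotypic_fixture_returns_to_baseline(self):
        counts, truth = make_domain_timecourse("homotypic", seed=3)
        df = domain_distribution(counts)
        assert df[df.time_bin >= 480].frac_peripheral.max() <= 0.25

    def test_baseline_pooled_central_fraction(self):
        counts, _ = make_domain_timecourse("none", seed=3)
        central, peripheral = pooled_domain_fractions(counts)
        assert central == pytest.approx(0.764)


class TestAnterogradeFlux:
    def _crossing_track(self, gid, t_cross, ts):
        # linear, crosses 0 at t_cross, stays in the last 50 um of shaft
        v = 0.1
        pos = np.clip(v * (ts - t_cross), -45, None)
        return Track(gid, ts, pos)

    def test_single_crossing_is_unit_vector(self):
        ts = np.arange(0, 601, 30.0)
        fs = anterograde_flux([self._crossing_track("a", 200, ts)], bin_s=60)
        assert fs.raw_counts.sum() == 1
        assert fs.normalized.mean() == pytest.approx(1.0)

    def test_constant_transport_normalizes_to_one(self):
        ts = np.arange(0, 601, 30.0)
        tracks = [
            self._crossing_track(f"g{k}", 30 + 60 * (k % 10), ts) for k in range(20)
        ]
        fs = anterograde_flux(tracks, bin_s=60)
        assert np.allclose(fs.raw_counts, 2)
        assert np.allclose(fs.normalized, 1.0)

    def test_all_zero_counts_flagged_undefined(self):
        ts = np.arange(0, 601, 30.0)
        fs = anterograde_flux([Track("a", ts, np.full(len(ts), -10.0))])
        assert not fs.defined and fs.normalized is None

    def test_ramping_crossings_nondecreasing_after_onset(self):
        ts = np.arange(0, 601, 30.0)
        tracks = []
        k = 0
        schedule = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]  # arrivals per 60-s bin
        for b, count in enumerate(schedule):
            for _ in range(count):
                tracks.append(self._crossing_track(f"g{k}", 30 + 60 * b, ts))
                k += 1
        fs = anterograde_flux(tracks, bin_s=60)
        assert np.all(np.diff(fs.raw_counts) >= 0)
        assert fs.normalized.mean() == pytest.approx(1.0)
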