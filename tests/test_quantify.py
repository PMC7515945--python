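"""ROI quantification, corrections, TBR and cohort statistics."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from climargin import imaging as im
from climargin import phantom as ph
from climargin import physics
from climargin import quantify as qt
from climargin.errors import ContractError, DomainError

from .oracles import roi_mean_loop

T0 = datetime(2020, 1, 15, 10, 0, tzinfo=timezone.utc)


def make_map(values, exposure=150.0, view="anterior", minutes_after=0.0):
    return im.RadianceMap(values=np.asarray(values, dtype=float),
                          settings=im.AcquisitionSettings(exposure, 8),
                          acquisition_time=T0 + timedelta(minutes=minutes_after),
                          view=view)


class TestRoiMean:
    def test_uniform_map_returns_value(self):
        roi = qt.ROI(np.ones((6, 6), dtype=bool))
        assert qt.roi_mean_radiance(make_map(np.full((6, 6), 7.5)), roi) == 7.5

    def test_four_pixel_arithmetic(self):
        values = np.zeros((4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        for k, (r, c) in enumerate([(0, 0), (1, 1), (2, 2), (3, 3)]):
            values[r, c] = k + 1
            mask[r, c] = True
        assert qt.roi_mean_radiance(make_map(values), qt.ROI(mask)) == 2.5

    def test_matches_naive_loop_on_random_mask(self):
        rng = np.random.default_rng(11)
        values = rng.random((32, 32)) * 100
        flat = rng.choice(32 * 32, size=100, replace=False)
        mask = np.zeros(32 * 32, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(32, 32)
        ours = qt.roi_mean_radiance(make_map(values), qt.ROI(mask))
        assert ours == pytest.approx(roi_mean_loop(values, mask), abs=1e-12)

    def test_empty_roi_rejected(self):
        with pytest.raises(DomainError):
            qt.ROI(np.zeros((4, 4), dtype=bool))


class TestCorrections:
    def test_decay_correct_identity_and_one_half_life(self):
        assert qt.decay_correct(10.0, T0, T0, 68.0) == 10.0
        later = T0 + timedelta(minutes=68)
        assert qt.decay_correct(10.0, later, T0, 68.0) == pytest.approx(20.0)

    @given(seconds=st.integers(0, 24_000), radiance=st.floats(0.01, 1e6))
    def test_decay_round_trip_inverts_decay_factor(self, seconds, radiance):
        t_min = seconds / 60.0
        decayed = radiance * physics.decay_factor(t_min, 68.0)
        restored = qt.decay_correct(decayed, T0 + timedelta(seconds=seconds),
                                    T0, 68.0)
        assert restored == pytest.approx(radiance, rel=1e-12)

    def test_activity_normalize_examples_and_involution(self):
        assert qt.activity_normalize(5.0, 100.0, 100.0) == 5.0
        assert qt.activity_normalize(5.0, 50.0, 100.0) == 10.0
        back = qt.activity_normalize(qt.activity_normalize(7.0, 83.0, 100.0),
                                     100.0, 83.0)
        assert back == pytest.approx(7.0, rel=1e-12)

    def test_non_positive_activity_rejected(self):
        with pytest.raises(DomainError):
            qt.activity_normalize(1.0, 0.0, 100.0)


class TestTBR:
    def _meas(self, value, view="anterior", minutes=10.0):
        return qt.RadianceMeasurement(raw_mean_radiance=value,
                                      decay_corrected=value, activity_corrected=value,
                                      elapsed_since_injection_min=minutes,
                                      roi_label="x", view=view)

    def test_ratio_arithmetic(self):
        assert qt.tbr(self._meas(4.0), self._meas(2.0)) == 2.0
        assert qt.tbr(self._meas(3.0), self._meas(3.0)) == 1.0

    @given(scale=st.floats(1e-3, 1e3), tumour=st.floats(0.1, 100.0),
           background=st.floats(0.1, 100.0))
    def test_common_scale_invariance(self, scale, tumour, background):
        base = qt.tbr(self._meas(tumour), self._meas(background))
        scaled = qt.tbr(self._meas(tumour * scale), self._meas(background * scale))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_mixed_frame_inputs_rejected(self):
        with pytest.raises(ContractError):
            qt.tbr(self._meas(4.0, view="left"), self._meas(2.0, view="right"))
        with pytest.raises(DomainError):
            qt.tbr(self._meas(4.0), self._meas(0.0))


class TestCohortSummary:
    def test_injected_activity_row_reproduced(self):
        mean, sd = qt.cohort_summary([118, 68, 88, 76, 65])
        assert round(mean) == 83
        assert round(sd) == 19

    def test_filtered_cleaved_tbr_row_reproduced(self):
        mean, sd = qt.cohort_summary([3.1, 2.2, 3.1, 5.9])
        assert round(mean, 1) == 3.6
        assert round(sd, 1) == 1.4

    def test_unfiltered_cleaved_tbr_row_reproduced(self):
        mean, sd = qt.cohort_summary([1.8, 2.6, 1.8])
        assert round(mean, 1) == 2.1
        assert round(sd, 1) == 0.4

    def test_single_value_has_zero_dispersion(self):
        assert qt.cohort_summary([4.2]) == (4.2, 0.0)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=12),
           st.floats(-50, 50))
    def test_mean_translates_sd_invariant(self, values, shift):
        m0, s0 = qt.cohort_summary(values)
        m1, s1 = qt.cohort_summary([v + shift for v in values])
        assert m1 == pytest.approx(m0 + shift, rel=1e-9, abs=1e-9)
        assert s1 == pytest.approx(s0, rel=1e-9, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            qt.cohort_summary([])


class TestPolygonROI:
    def test_square_polygon_matches_slicing(self):
        roi = qt.polygon_roi((10, 10), [(2, 2), (2, 7), (7, 7), (7, 2)])
        expected = np.zeros((10, 10), dtype=bool)
        expected[2:7, 2:7] = True
        assert np.array_equal(roi.mask, expected)

    def test_nonconvex_polygon_matches_shapely_oracle(self):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point, Polygon
        verts = [(1, 1), (1, 14), (14, 14), (14, 8), (6, 8), (6, 1)]
        roi = qt.polygon_roi((16, 16), verts)
        poly = Polygon([(r, c) for r, c in verts])
        for i in range(16):
            for j in range(16):
                assert roi.mask[i, j] == poly.contains(Point(i + 0.5, j + 0.5))


class TestParameterRecovery:
    def test_surface_lesion_tbr_recovers_true_ratio_within_10pc(self):
        """Low-noise surface lesion: measured TBR ~ configured uptake ratio.

        The residual deficit is the physically expected positron-range
        blur of the hotspot peak.
        """
        camera = ph.CameraModel(sensor_shape=(1024, 1024),
                                counts_per_radiance_s=1e-4,
                                read_noise_sigma=1.0,
                                gamma_strike_rate_per_s=0.0, defective_pixels=())
        phantom, start = ph.example_phantom(lesion_depths={"anterior": 0.0},
                                            activity_ratio=6.0,
                                            lateral_sigma_mm=12.0, camera=camera)
        truth = ph.GroundTruth.from_phantom(phantom)
        settings = im.AcquisitionSettings(150, 2, "none")
        t_roi = qt.ROI(truth.tumour_mask("anterior", 2, level=0.95), "tumour")
        b_roi = qt.ROI(truth.background_mask("anterior", 2, level=0.02),
                       "background")
        tbrs = []
        for seed in range(20):
            frame = ph.render_view(phantom, "anterior", settings, start, seed)
            bg = ph.render_background(phantom, settings, start, 1000 + seed)
            rmap = im.process_frame(frame, bg)
            tbrs.append(qt.tbr_from_map(rmap, t_roi, b_roi))
        assert np.mean(tbrs) == pytest.approx(6.0, rel=0.10)
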