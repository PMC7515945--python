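"""Specimen phantom: noise model, determinism, ground truth, study assembly."""

import numpy as np
import pytest
from scipy import stats

from climargin import phantom as ph
from climargin.errors import DomainError
from climargin.imaging import AcquisitionSettings, bin_raster


def _phantom(camera, depths=None, **kwargs):
    return ph.example_phantom(lesion_depths=depths or {}, camera=camera, **kwargs)


class TestRenderView:
    def test_noise_free_lesionless_frame_is_uniform_benign_expectation(self, quiet_camera):
        phantom, start = _phantom(quiet_camera)
        settings = AcquisitionSettings(150, 2, "none")
        frame = ph.render_view(phantom, "left", settings, start, seed=0)
        expected = phantom.expected_counts("left", settings, start)
        analytic = bin_raster(np.rint(expected), 2)
        assert np.array_equal(frame.counts, analytic)
        assert np.unique(frame.counts).size == 1

    def test_same_seed_is_bit_identical(self, small_camera):
        phantom, start = _phantom(small_camera, {"anterior": 0.0})
        settings = AcquisitionSettings(60, 2, "none")
        a = ph.render_view(phantom, "anterior", settings, start, seed=7)
        b = ph.render_view(phantom, "anterior", settings, start, seed=7)
        c = ph.render_view(phantom, "anterior", settings, start, seed=8)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_acquisition_before_injection_rejected(self, quiet_camera):
        phantom, start = _phantom(quiet_camera)
        early = phantom.injection_time - np.timedelta64(1, "m").item()
        with pytest.raises(DomainError):
            ph.render_view(phantom, "left", AcquisitionSettings(30, 2, "none"),
                           early, seed=0)

    @pytest.mark.parametrize("depth,expect_similar", [(6.0, False), (0.0, True)])
    def test_filter_suppresses_deep_but_not_surface_contrast(self, quiet_camera,
                                                             depth, expect_similar):
        phantom, start = _phantom(quiet_camera, {"anterior": depth})

        def contrast(optical_filter):
            fld = phantom.expected_radiance("anterior", optical_filter, start)
            benign = fld.min()
            return (fld.max() - benign) / benign

        c_unf, c_fil = contrast("none"), contrast("shortpass_550")
        if expect_similar:
            assert c_fil == pytest.approx(c_unf, rel=0.10)
        else:
            assert c_fil < 0.25 * c_unf

    def test_binning_conserves_counts_before_clipping(self):
        # same seed: the unbinned noise realisation is identical, so the
        # 8x8-binned frame must equal the block sum of the unbinned one
        # (no saturated pixels, so clipping never engages)
        camera = ph.CameraModel(sensor_shape=(64, 64), defective_pixels=(),
                                counts_per_radiance_s=1e-4)
        phantom, start = _phantom(camera, {"anterior": 0.0})
        unbinned = ph.render_view(phantom, "anterior",
                                  AcquisitionSettings(60, 1, "none"), start, seed=3)
        binned = ph.render_view(phantom, "anterior",
                                AcquisitionSettings(60, 8, "none"), start, seed=3)
        assert np.array_equal(bin_raster(unbinned.counts.astype(int), 8),
                              binned.counts)

    def test_decay_halves_expected_signal_after_one_half_life(self, quiet_camera):
        phantom, start = _phantom(quiet_camera, {"anterior": 0.0})
        settings = AcquisitionSettings(150, 2, "none")
        later = start + np.timedelta64(68, "m").item()
        now = phantom.expected_counts("anterior", settings, start)
        after = phantom.expected_counts("anterior", settings, later)
        assert np.allclose(after, 0.5 * now, rtol=1e-12)

    def test_pixel_mean_converges_to_analytic_expectation(self):
        camera = ph.CameraModel(sensor_shape=(8, 8), read_noise_sigma=5.0,
                                dark_offset=100.0, gamma_strike_rate_per_s=0.0,
                                defective_pixels=(), counts_per_radiance_s=1e-3)
        phantom, start = _phantom(camera)
        settings = AcquisitionSettings(150, 1, "none")
        expected = phantom.expected_counts("left", settings, start)[0, 0]
        assert expected >= 100
        total = 0.0
        for seed in range(10_000):
            total += ph.render_view(phantom, "left", settings, start,
                                    seed=seed).counts[0, 0]
        mean = total / 10_000 - camera.dark_offset
        assert mean == pytest.approx(expected, rel=0.01)


class TestRenderBackground:
    def test_noise_free_background_is_constant_dark_offset(self):
        camera = ph.CameraModel(sensor_shape=(32, 32), read_noise_sigma=0.0,
                                dark_offset=100.0, gamma_strike_rate_per_s=0.0,
                                defective_pixels=(), shot_noise=False)
        phantom, _ = _phantom(camera)
        frame = ph.render_background(phantom, AcquisitionSettings(150, 1, "none"))
        assert np.all(frame.counts == 100)

    def test_defective_pixel_saturated_on_every_frame(self, small_camera):
        phantom, _ = _phantom(small_camera)
        frame = ph.render_background(phantom, AcquisitionSettings(150, 1, "none"),
                                     seed=9)
        assert frame.counts[10, 40] == small_camera.full_scale

    def test_mean_of_100_backgrounds_recovers_dark_offset(self):
        camera = ph.CameraModel(sensor_shape=(16, 16), read_noise_sigma=5.0,
                                dark_offset=100.0, gamma_strike_rate_per_s=0.0,
                                defective_pixels=())
        phantom, _ = _phantom(camera)
        vals = [ph.render_background(phantom, AcquisitionSettings(30, 1, "none"),
                                     seed=s).counts[3, 3]
                for s in range(100)]
        assert np.mean(vals) == pytest.approx(100.0,
                                              abs=3 * camera.read_noise_sigma / 10)

    def test_gamma_strike_count_is_poisson(self):
        camera = ph.CameraModel(sensor_shape=(64, 64), read_noise_sigma=0.5,
                                dark_offset=100.0, gamma_strike_rate_per_s=0.04,
                                gamma_strike_mean_amplitude=2000.0,
                                defective_pixels=())
        phantom, _ = _phantom(camera)
        settings = AcquisitionSettings(100, 1, "none")
        mean_rate = camera.gamma_strike_rate_per_s * settings.exposure_s  # 4.0
        counts = []
        for seed in range(500):
            frame = ph.render_background(phantom, settings, seed=seed)
            counts.append(int(np.sum(frame.counts > 150)))
        counts = np.array(counts)
        # chi-square goodness of fit against Poisson(4), pooling sparse tails
        edges = [0, 1, 2, 3, 4, 5, 6, 7, 8]
        observed = np.array([np.sum(counts == k) for k in edges[:-1]]
                            + [np.sum(counts >= edges[-1])])
        probs = np.array([stats.poisson.pmf(k, mean_rate) for k in edges[:-1]]
                         + [stats.poisson.sf(edges[-1] - 1, mean_rate)])
        _, p = stats.chisquare(observed, probs * len(counts))
        assert p > 0.01


class TestStudyAndGroundTruth:
    def test_six_views_two_filters_frame_count_and_budget(self, small_camera):
        phantom, start = _phantom(small_camera, {"anterior": 0.0})
        protocol = [AcquisitionSettings(150, 8, "none"),
                    AcquisitionSettings(150, 8, "shortpass_550")]
        study, truth = ph.render_study(phantom, protocol, start, seed=1)
        assert len(study.specimen_frames) == 12
        assert len(study.background_frames) == 2
        assert study.total_acquisition_minutes <= 45.0
        assert truth.labels["anterior"] == "PSM"
        times = [f.acquisition_time for f in study.specimen_frames]
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))

    def test_per_view_backgrounds_mode(self, small_camera):
        phantom, start = _phantom(small_camera)
        protocol = [AcquisitionSettings(30, 2, "none")]
        study, _ = ph.render_study(phantom, protocol, start, seed=1,
                                   backgrounds="per_view")
        assert len(study.background_frames) == 6
        frame = study.frame("basal", "none")
        assert study.background_for(frame).view == "basal"

    @pytest.mark.parametrize("depth,label",
                             [(0.0, "PSM"), (0.05, "CLOSE"), (0.2, "NSM"),
                              (3.0, "NSM")])
    def test_margin_labels_follow_depth(self, quiet_camera, depth, label):
        phantom, _ = _phantom(quiet_camera, {"apical": depth})
        truth = ph.GroundTruth.from_phantom(phantom)
        assert truth.labels["apical"] == label
        assert truth.labels["left"] == "NSM"

    def test_study_rerender_is_reproducible(self, small_camera):
        phantom, start = _phantom(small_camera, {"anterior": 0.0})
        protocol = [AcquisitionSettings(30, 2, "none")]
        a, _ = ph.render_study(phantom, protocol, start, seed=12)
        b, _ = ph.render_study(phantom, protocol, start, seed=12)
        for fa, fb in zip(a.specimen_frames + a.background_frames,
                          b.specimen_frames + b.background_frames):
            assert np.array_equal(fa.counts, fb.counts)
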