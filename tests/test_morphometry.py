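"""Morphometry: peak detection, length rules, group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sarcotrack import morphometry as morph, synthetic as syn


def _profile(intensities, px=0.05, channel="phalloidin"):
    intensities = np.asarray(intensities, dtype=float)
    return morph.IntensityProfile(
        np.arange(intensities.size) * px, intensities, pixel_size=px, channel=channel
    )


class TestIntensityProfile:
    def test_non_uniform_spacing_rejected(self):
        pos = np.arange(20) * 0.05
        pos[10] += 0.001
        with pytest.raises(ValueError, match="uniform"):
            morph.IntensityProfile(pos, np.ones(20), pixel_size=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="16 samples"):
            morph.IntensityProfile(np.arange(8) * 0.05, np.ones(8), pixel_size=0.05)


class TestExtractLineProfile:
    def test_constant_image_gives_constant_profile(self):
        img = np.full((30, 40), 7.5)
        prof = morph.extract_line_profile(img, [(15, 2), (15, 38)], width_px=3)
        assert np.allclose(prof.intensities, 7.5)

    def test_width_irrelevant_on_translation_invariant_stripes(self, default_truth):
        img = syn.gen_striation_image(default_truth, fibril_count=1, fibril_width_px=11)
        r0, r1 = img.fibril_rows[0]
        row = (r0 + r1) / 2 * img.pixel_size
        end = (img.image.shape[1] - 1) * img.pixel_size
        p1 = morph.extract_line_profile(img.image, [(row, 0), (row, end)], 1, img.pixel_size)
        p5 = morph.extract_line_profile(img.image, [(row, 0), (row, end)], 5, img.pixel_size)
        assert np.allclose(p1.intensities, p5.intensities, atol=1e-9)

    def test_out_of_bounds_polyline_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="outside"):
            morph.extract_line_profile(img, [(5, 5), (5, 50)])

    def test_degenerate_polyline_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="degenerate"):
            morph.extract_line_profile(img, [(5, 5), (5, 5)])


class TestPeakDetection:
    def test_flat_profile_yields_no_measurement(self):
        assert morph.detect_z_discs(_profile(np.ones(64))) is None

    def test_single_peak_yields_no_measurement(self):
        y = np.exp(-0.5 * ((np.arange(64) - 32) / 3.0) ** 2)
        assert morph.detect_z_discs(_profile(y)) is None
        assert morph.detect_m_lines(_profile(y, channel="obscurin")) is None

    def test_noisy_positions_within_one_pixel_of_truth(self, default_truth, noisy_profile):
        z = morph.detect_z_discs(noisy_profile)
        sl = default_truth.sarcomere_length
        margin = np.ceil(sl / 2 / default_truth.pixel_size) * default_truth.pixel_size
        grid = margin + np.arange(9) * sl
        assert len(z) == 9
        assert np.max(np.abs(z - grid)) < default_truth.pixel_size

    def test_m_lines_from_phalloidin_troughs_midway_between_z(self, default_truth):
        prof = syn.gen_striation_profile(default_truth, 6, noise_sd=0.0)
        z = morph.detect_z_discs(prof)
        m = morph.detect_m_lines(prof)  # trough detection on inverted profile
        mids = z[:-1] + np.diff(z) / 2
        assert len(m) == len(mids)
        assert np.max(np.abs(m - mids)) < default_truth.pixel_size

    def test_detection_translation_invariant(self, noisy_profile):
        k = 7  # pixels
        shifted = morph.IntensityProfile(
            noisy_profile.positions + k * noisy_profile.pixel_size,
            noisy_profile.intensities,
            pixel_size=noisy_profile.pixel_size,
        )
        z0 = morph.detect_z_discs(noisy_profile)
        z1 = morph.detect_z_discs(shifted)
        assert np.allclose(z1 - z0, k * noisy_profile.pixel_size, atol=1e-9)

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1000.0])
    def test_lengths_invariant_under_intensity_scaling(self, noisy_profile, scale):
        scaled = morph.IntensityProfile(
            noisy_profile.positions,
            noisy_profile.intensities * scale,
            pixel_size=noisy_profile.pixel_size,
        )
        assert np.allclose(
            morph.detect_z_discs(noisy_profile), morph.detect_z_discs(scaled), atol=1e-9
        )


class TestMeasureSarcomereLengths:
    def test_consecutive_differences(self):
        out = morph.measure_sarcomere_lengths([0.0, 3.36, 6.72])
        assert np.allclose(out, [3.36, 3.36])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            morph.measure_sarcomere_lengths([0.0, 6.72, 3.36])

    def test_min_n_returns_no_measurement(self):
        assert morph.measure_sarcomere_lengths([0.0, 3.36], min_n=2) is None

    def test_m_to_m_recovery_of_bent_day6_length(self):
        truth = syn.StriationTruth.from_period(3.10, 0.16)
        noise = 0.05 * (truth.z_peak_level - truth.background)
        prof = syn.gen_mline_profile(truth, 8, noise_sd=noise, seed=3)
        lengths = morph.measure_sarcomere_lengths(morph.detect_m_lines(prof))
        assert abs(lengths.mean() - 3.10) < truth.pixel_size


class TestThinFilamentLength:
    def test_trapezoid_ramp_midpoint_is_analytic(self):
        # plateau 1.0 out to 1.2 µm from each Z-disc, linear ramp to 0.1
        # over 0.2 µm: the half crossing sits at 1.3 µm, so TFL = 1.3
        px = 0.01
        sl = 3.0
        n = int(round(sl / px)) + 1
        x = np.arange(n) * px
        d = np.minimum(x, sl - x)  # distance to nearest Z-disc
        y = np.interp(d, [0.0, 1.2, 1.4, sl / 2], [1.0, 1.0, 0.1, 0.1])
        y[0] = y[-1] = 2.0  # sharp Z-disc spikes at the boundaries
        prof = _profile(y, px=px)
        tfl, hz, degenerate = morph.measure_thin_filament_length(
            prof, (0.0, sl), smooth_sigma=0.0
        )
        assert not degenerate
        assert tfl == pytest.approx(1.3, abs=px)
        assert hz == pytest.approx(sl - 2 * 1.3, abs=2 * px)

    def test_symmetric_sarcomere_gives_centred_h_zone(self, default_truth):
        prof = syn.gen_striation_profile(default_truth, 6, noise_sd=0.0)
        z = morph.detect_z_discs(prof)
        tfl, hz, _ = morph.measure_thin_filament_length(prof, (z[2], z[3]))
        # symmetric geometry: crossings equidistant from both Z-discs
        assert 2 * tfl + hz == pytest.approx(z[3] - z[2], abs=1e-9)
        assert tfl == pytest.approx((z[3] - z[2] - hz) / 2, abs=1e-9)

    def test_noisy_round_trip_within_one_pixel(self, default_truth):
        noise = 0.05 * (default_truth.z_peak_level - default_truth.background)
        tfls, hzs = [], []
        for seed in range(1, 11):
            prof = syn.gen_striation_profile(default_truth, 8, noise_sd=noise, seed=seed)
            z = morph.detect_z_discs(prof)
            for pair in zip(z[:-1], z[1:]):
                tfl, hz, _ = morph.measure_thin_filament_length(prof, pair)
                tfls.append(tfl)
                hzs.append(hz)
        assert abs(np.mean(tfls) - 1.60) < default_truth.pixel_size
        assert abs(np.mean(hzs) - 0.16) < default_truth.pixel_size

    def test_degenerate_h_zone_flagged(self):
        truth = syn.StriationTruth(3.2, 1.6, 0.0, psf_sigma=0.0)
        prof = syn.gen_striation_profile(truth, 5, noise_sd=0.0)
        z = morph.detect_z_discs(prof)
        tfl, hz, degenerate = morph.measure_thin_filament_length(prof, (z[1], z[2]))
        assert degenerate and hz == 0.0
        assert tfl == pytest.approx((z[2] - z[1]) / 2)

    def test_non_adjacent_pair_rejected(self, default_truth):
        prof = syn.gen_striation_profile(default_truth, 6, noise_sd=0.0)
        z = morph.detect_z_discs(prof)
        with pytest.raises(ValueError, match="adjacent"):
            morph.measure_thin_filament_length(prof, (z[0], z[2]))


class TestGroupStats:
    def test_constant_group(self):
        g = morph.summarize_group([3.0, 3.0, 3.0])
        assert (g.n, g.mean, g.sd) == (3, 3.0, 0.0)

    def test_single_value_flagged(self):
        g = morph.summarize_group([3.36])
        assert g.sd == 0.0 and not g.sd_defined

    def test_sem_definition(self, rng):
        sample = rng.normal(3.36, 0.1, size=30)
        g = morph.summarize_group(sample)
        assert g.sem == pytest.approx(g.sd / np.sqrt(30))
        assert abs(g.mean - 3.36) < 3 * g.sem + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            morph.summarize_group([])


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        a = [3.3, 3.4, 3.5, 3.6]
        res = morph.compare_groups(a, a)
        assert res.p == pytest.approx(1.0)
        assert res.stars == "ns"

    @pytest.mark.parametrize(
        "p,stars", [(0.01, "*"), (0.001, "**"), (1e-5, "***"), (0.2, "ns"),
                    (0.05, "ns"), (0.005, "*"), (0.0005, "**")]
    )
    def test_star_thresholds(self, p, stars):
        assert morph.star_code(p) == stars

    def test_t_statistic_matches_hand_computation(self):
        # pooled-variance Student's t computed from first principles
        a = np.array([3.1, 3.3, 3.2])
        b = np.array([3.6, 3.8, 3.7])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = morph.compare_groups(a, b)
        assert res.t == pytest.approx(expected)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            morph.compare_groups([3.0], [3.1, 3.2])


class TestPercentChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(3.41, 3.76, 10.3), (3.35, 3.57, 6.6), (5.0, 5.0, 0.0)],
    )
    def test_reported_values(self, before, after, expected):
        assert round(morph.percent_change(before, after), 1) == expected

    def test_control_change_rounds_to_one_percent_decrease(self):
        assert round(morph.percent_change(3.36, 3.33)) == -1

    def test_non_positive_before_rejected(self):
        with pytest.raises(ValueError):
            morph.percent_change(0.0, 3.0)

    @given(
        before=st.floats(0.1, 100), frac=st.floats(-0.9, 9.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inverts_exactly(self, before, frac):
        after = before * (1 + frac)
        pct = morph.percent_change(before, after)
        assert before * (1 + pct / 100) == pytest.approx(after, rel=1e-9)


class TestGeometricClosure:
    def test_sl_equals_twice_tfl_plus_hz_within_two_pixels(self, default_truth):
        noise = 0.05 * (default_truth.z_peak_level - default_truth.background)
        for seed in (1, 2, 3):
            prof = syn.gen_striation_profile(default_truth, 8, noise_sd=noise, seed=seed)
            z = morph.detect_z_discs(prof)
            sls = morph.measure_sarcomere_lengths(z)
            for sl, pair in zip(sls, zip(z[:-1], z[1:])):
                tfl, hz, _ = morph.measure_thin_filament_length(prof, pair)
                assert abs(sl - (2 * tfl + hz)) < 2 * default_truth.pixel_size

    def test_z_to_z_and_m_to_m_agree_noise_free(self, default_truth):
        pz = syn.gen_striation_profile(default_truth, 6, noise_sd=0.0)
        pm = syn.gen_mline_profile(default_truth, 6, noise_sd=0.0)
        mz = morph.measure_sarcomere_lengths(morph.detect_z_discs(pz)).mean()
        mm = morph.measure_sarcomere_lengths(morph.detect_m_lines(pm)).mean()
        assert abs(mz - mm) < default_truth.pixel_size
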