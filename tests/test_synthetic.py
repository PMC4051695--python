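"""Generators: construction guarantees, closed forms, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from sarcotrack import geotaxis, morphometry as morph, synthetic as syn


class TestStriationTruth:
    def test_closure_identity_enforced(self):
        with pytest.raises(ValueError, match="SL = 2\\*TFL \\+ HZ"):
            syn.StriationTruth(3.36, 1.5, 0.16)

    @pytest.mark.parametrize("sl,hz", [(3.10, 0.16), (3.76, 0.2), (3.2, 0.0)])
    def test_from_period_satisfies_closure(self, sl, hz):
        t = syn.StriationTruth.from_period(sl, hz)
        assert 2 * t.thin_filament_length + t.h_zone_width == pytest.approx(sl, abs=1e-12)

    def test_level_ordering_enforced(self):
        with pytest.raises(ValueError, match="levels"):
            syn.StriationTruth.from_period(3.36, 0.16, filament_level=1.5)


class TestStriationProfile:
    def test_noise_free_maxima_at_exact_spacing(self):
        truth = syn.StriationTruth.from_period(3.4, 0.16, psf_sigma=0.0)
        prof = syn.gen_striation_profile(truth, 5, noise_sd=0.0)
        z = morph.detect_z_discs(prof)
        assert len(z) == 6
        assert np.allclose(np.diff(z), 3.4, atol=1e-9)

    def test_degenerate_h_zone_has_no_interior_trough(self):
        truth = syn.StriationTruth(3.2, 1.6, 0.0, psf_sigma=0.0)
        prof = syn.gen_striation_profile(truth, 4, noise_sd=0.0)
        # away from the Z-disc peaks the profile never dips below the plateau
        z = morph.detect_z_discs(prof)
        interior = (prof.positions > z[0] + 0.5) & (prof.positions < z[-1] - 0.5)
        assert prof.intensities[interior].min() >= truth.filament_level - 1e-9

    def test_unresolvable_trough_rejected(self):
        truth = syn.StriationTruth.from_period(3.36, 0.04, pixel_size=0.05, psf_sigma=0.0)
        with pytest.raises(ValueError, match="unresolvable"):
            syn.gen_striation_profile(truth, 4)

    def test_negative_noise_rejected(self, default_truth):
        with pytest.raises(ValueError, match="noise_sd"):
            syn.gen_striation_profile(default_truth, 4, noise_sd=-1.0)

    def test_truth_attached(self, noisy_profile, default_truth):
        assert noisy_profile.truth == default_truth

    def test_noisy_round_trip_recovers_length_within_pixel(self):
        truth = syn.StriationTruth.from_period(3.36, 0.16)
        noise = 0.05 * (truth.z_peak_level - truth.background)
        prof = syn.gen_striation_profile(truth, 8, noise_sd=noise, seed=1)
        lengths = morph.measure_sarcomere_lengths(morph.detect_z_discs(prof))
        assert abs(lengths.mean() - 3.36) < truth.pixel_size


class TestMlineProfile:
    def test_noise_free_peak_spacing_equals_sl(self, default_truth):
        prof = syn.gen_mline_profile(default_truth, 6, noise_sd=0.0)
        m = morph.detect_m_lines(prof)
        assert np.allclose(np.diff(m), default_truth.sarcomere_length, atol=1e-3)

    def test_m_peaks_offset_half_period_from_z_peaks(self, default_truth):
        pz = syn.gen_striation_profile(default_truth, 6, noise_sd=0.0)
        pm = syn.gen_mline_profile(default_truth, 6, noise_sd=0.0)
        z = morph.detect_z_discs(pz)
        m = morph.detect_m_lines(pm)
        offset = m - z[: len(m)]
        assert np.allclose(offset, default_truth.sarcomere_length / 2, atol=1e-3)

    def test_noisy_m_to_m_round_trip(self, default_truth):
        noise = 0.05 * (default_truth.z_peak_level - default_truth.background)
        prof = syn.gen_mline_profile(default_truth, 8, noise_sd=noise, seed=2)
        lengths = morph.measure_sarcomere_lengths(morph.detect_m_lines(prof))
        assert abs(lengths.mean() - default_truth.sarcomere_length) < default_truth.pixel_size


class TestStriationImage:
    def test_line_profile_matches_1d_generator(self, default_truth):
        img = syn.gen_striation_image(default_truth, fibril_count=1, fibril_width_px=5)
        r0, r1 = img.fibril_rows[0]
        row_um = (r0 + r1) / 2 * img.pixel_size
        end_um = (img.image.shape[1] - 1) * img.pixel_size
        prof = morph.extract_line_profile(
            img.image, [(row_um, 0.0), (row_um, end_um)], width_px=3,
            pixel_size=img.pixel_size,
        )
        template = img.template_profile.intensities
        assert np.allclose(prof.intensities, template, atol=1e-6)

    def test_rotation_by_90_degrees_preserves_measurements(self, default_truth):
        img0 = syn.gen_striation_image(default_truth, fibril_count=1, fibril_width_px=5)
        img90 = syn.gen_striation_image(
            default_truth, fibril_count=1, fibril_width_px=5, orientation=90
        )
        assert np.allclose(img90.image, np.rot90(img0.image))

    def test_multiple_fibrils_independently_recoverable(self, default_truth):
        img = syn.gen_striation_image(default_truth, fibril_count=3, fibril_width_px=5)
        end_um = (img.image.shape[1] - 1) * img.pixel_size
        for r0, r1 in img.fibril_rows:
            row_um = (r0 + r1) / 2 * img.pixel_size
            prof = morph.extract_line_profile(
                img.image, [(row_um, 0.0), (row_um, end_um)], pixel_size=img.pixel_size
            )
            lengths = morph.measure_sarcomere_lengths(morph.detect_z_discs(prof))
            assert abs(lengths.mean() - default_truth.sarcomere_length) < img.pixel_size

    def test_zero_area_geometry_rejected(self, default_truth):
        with pytest.raises(ValueError):
            syn.gen_striation_image(default_truth, fibril_count=0)


class TestPulseChase:
    def test_plateau_when_not_decaying(self, egfp_kinetics):
        series = syn.gen_pulse_chase(egfp_kinetics, [0, 100, 150, 200], 10, noise_sd=0.0)
        assert series.z_intensity[-1].mean() == pytest.approx(egfp_kinetics.peak)

    def test_half_life_definition(self, act88f_kinetics):
        k = act88f_kinetics
        t = k.rise_end + k.decay_halflife
        series = syn.gen_pulse_chase(k, [0, t], 5, noise_sd=0.0)
        expected = k.baseline + (k.peak - k.baseline) / 2
        assert series.z_intensity[1].mean() == pytest.approx(expected)

    def test_empty_timepoints_rejected(self, act88f_kinetics):
        with pytest.raises(ValueError, match="timepoints"):
            syn.gen_pulse_chase(act88f_kinetics, [], 5)

    def test_body_intensity_scales_with_body_fraction(self, act88f_kinetics):
        series = syn.gen_pulse_chase(act88f_kinetics, [50.0], 5, noise_sd=0.0)
        ratio = series.body_intensity[0].mean() / series.z_intensity[0].mean()
        assert ratio == pytest.approx(act88f_kinetics.body_fraction)


class TestCtTable:
    DESIGN = syn.QpcrDesign(
        targets=("tgt",),
        reference="ref",
        conditions=(("wt", 0), ("wt", 6)),
        expression={("tgt", "wt", 0): 1.0, ("tgt", "wt", 6): 0.25},
        base_ct={"tgt": 20.0, "ref": 15.0},
        replicate_sd=0.0,
    )

    def test_quarter_expression_costs_two_cycles(self):
        table = syn.gen_ct_table(self.DESIGN, n_replicates=1)
        ct = table.set_index(["gene", "day"])["ct"]
        assert ct.loc[("tgt", 6)] - ct.loc[("tgt", 0)] == pytest.approx(2.0)
        assert ct.loc[("ref", 6)] == pytest.approx(ct.loc[("ref", 0)])

    def test_unit_expression_everywhere_gives_constant_ct(self):
        design = syn.QpcrDesign(
            targets=("tgt",), reference="ref", conditions=(("wt", 0), ("wt", 6)),
            expression={("tgt", "wt", 0): 1.0, ("tgt", "wt", 6): 1.0},
            base_ct={"tgt": 20.0, "ref": 15.0}, replicate_sd=0.0,
        )
        table = syn.gen_ct_table(design, n_replicates=2)
        assert table.groupby("gene")["ct"].nunique().eq(1).all()

    def test_non_positive_expression_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            syn.QpcrDesign(
                targets=("tgt",), reference="ref", conditions=(("wt", 0),),
                expression={("tgt", "wt", 0): 0.0},
                base_ct={"tgt": 20.0, "ref": 15.0},
            )


class TestGeotaxisGenerator:
    @pytest.mark.parametrize("p,score", [(1.0, 1.0), (0.0, 0.0)])
    def test_deterministic_extremes(self, p, score):
        design = syn.ClimbingDesign(
            days=(0, 3), p_success=(p, p), n_vials=3, flies_per_vial=10, tech_reps=2
        )
        data = syn.gen_geotaxis(design, seed=0)
        assert (data["successes"] / data["n_flies"] == score).all()

    def test_empirical_mean_converges_to_p(self):
        # n_vials * tech_reps * flies = 1000 trials per day
        design = syn.ClimbingDesign(
            days=(0,), p_success=(0.6,), n_vials=20, flies_per_vial=10, tech_reps=5
        )
        data = syn.gen_geotaxis(design, seed=3)
        frac = data["successes"] / data["n_flies"]
        se = np.sqrt(0.6 * 0.4 / (20 * 10 * 5))
        assert abs(frac.mean() - 0.6) < 3 * se


class TestScreenFixture:
    def test_class_counts_round_trip(self):
        fixture = syn.gen_screen_fixture((5, 13, 28, 86), seed=4)
        summary = geotaxis.summarize_screen(fixture.genes)
        assert summary["counts"] == {
            "Severe": 5, "Intermediate": 13, "Weak": 28, "None": 86,
        }
        assert summary["total"] == 132 and summary["hits"] == 46

    def test_all_none_fixture(self):
        fixture = syn.gen_screen_fixture((0, 0, 0, 10), seed=5)
        assert all(g.day_of_loss is None for g in fixture.genes)

    def test_day_of_loss_on_grid_and_in_window(self):
        fixture = syn.gen_screen_fixture((5, 5, 5, 0), seed=6)
        for g in fixture.genes:
            assert g.day_of_loss in geotaxis.DEFAULT_ASSAY_DAYS
            assert geotaxis.classify_severity(g.day_of_loss) == g.severity

    def test_network_size_matches_design(self):
        fixture = syn.gen_screen_fixture((2, 2, 2, 2), seed=7, n_edges=11)
        assert len(fixture.edges) == 11
        assert len(fixture.genes) == 8

    def test_annotated_genes_in_gene_list(self):
        fixture = syn.gen_screen_fixture((3, 3, 3, 3), seed=8)
        ids = {g.gene for g in fixture.genes}
        assert set(fixture.go_annotations) <= ids


class TestReproducibility:
    def test_profile_generator_bit_reproducible(self, default_truth):
        a = syn.gen_striation_profile(default_truth, 5, noise_sd=0.05, seed=11)
        b = syn.gen_striation_profile(default_truth, 5, noise_sd=0.05, seed=11)
        assert np.array_equal(a.intensities, b.intensities)

    def test_tabular_generators_bit_reproducible(self, act88f_kinetics):
        d = TestCtTable.DESIGN
        design = syn.QpcrDesign(
            targets=d.targets, reference=d.reference, conditions=d.conditions,
            expression=d.expression, base_ct=d.base_ct, replicate_sd=0.2,
        )
        pd.testing.assert_frame_equal(
            syn.gen_ct_table(design, 3, seed=9), syn.gen_ct_table(design, 3, seed=9)
        )
        climb = syn.ClimbingDesign.linear_decline(0.8, 0.2, n_vials=2, tech_reps=2)
        pd.testing.assert_frame_equal(
            syn.gen_geotaxis(climb, seed=9), syn.gen_geotaxis(climb, seed=9)
        )
        s1 = syn.gen_pulse_chase(act88f_kinetics, [0, 50, 100], 5, noise_sd=2.0, seed=9)
        s2 = syn.gen_pulse_chase(act88f_kinetics, [0, 50, 100], 5, noise_sd=2.0, seed=9)
        for a, b in zip(s1.z_intensity, s2.z_intensity):
            assert np.array_equal(a, b)
        f1 = syn.gen_screen_fixture((2, 2, 2, 2), seed=9)
        f2 = syn.gen_screen_fixture((2, 2, 2, 2), seed=9)
        assert f1 == f2
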