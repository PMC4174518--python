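"""Generator determinism, planted-truth consistency and end-to-end recovery."""

import numpy as np
import pytest
from scipy import stats

from dhmwound import (
    AssaySpec,
    SpherePopulationSpec,
    ValidationError,
    WoundGeometry,
    compute_frame_metrics,
    encode_assay_holograms,
    gap_coverage_series,
    make_sphere_image,
    make_sphere_population,
    make_wound_assay,
    reconstruct_phase,
    segment_cells,
    unwrap_phase,
)


class TestMakeSphereImage:
    def test_peak_matches_closed_form(self, cfg):
        img = make_sphere_image(11.7, 1.3678, cfg, field_shape=(128, 128))
        assert img.values.max() == pytest.approx(7.96, abs=0.01)

    def test_index_matched_sphere_is_blank(self, cfg):
        img = make_sphere_image(7.2, cfg.n_medium, cfg, field_shape=(64, 64))
        assert np.all(img.values == 0.0)

    def test_seed_determinism(self, cfg):
        a = make_sphere_image(7.2, 1.3713, cfg, noise_sd_rad=0.1, seed=42)
        b = make_sphere_image(7.2, 1.3713, cfg, noise_sd_rad=0.1, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_clipped_footprint_rejected(self, cfg):
        with pytest.raises(ValidationError, match="clipped"):
            make_sphere_image(20.0, 1.3713, cfg, field_shape=(64, 64))


class TestMakeSpherePopulation:
    def test_sample_means_near_population_means(self, cfg):
        spec = SpherePopulationSpec(n_cells=89, seed=7)
        _, truth = make_sphere_population(spec, cfg)
        # CLT bound on the generator itself
        assert abs(truth["radius_um"].mean() - 7.2) < 2 * 1.2 / np.sqrt(89)
        assert len(truth) == 89

    def test_zero_sd_gives_identical_cells(self, cfg):
        spec = SpherePopulationSpec(n_cells=5, radius_sd_um=0.0, n_cell_sd=0.0, seed=1)
        _, truth = make_sphere_population(spec, cfg)
        assert truth["radius_um"].nunique() == 1
        assert truth["n_cell"].nunique() == 1

    def test_truncation_bounds_respected(self, cfg):
        spec = SpherePopulationSpec(
            n_cells=200, radius_mean_um=1.5, radius_sd_um=1.0,
            n_cell_mean=1.341, n_cell_sd=0.002, seed=3,
        )
        _, truth = make_sphere_population(spec, cfg, field_shape=(96, 96))
        assert (truth["radius_um"] > 1.0).all()
        assert (truth["n_cell"] > cfg.n_medium + 0.001).all()

    def test_truth_mass_consistent_with_volume(self, cfg):
        _, truth = make_sphere_population(SpherePopulationSpec(n_cells=10, seed=5), cfg)
        dn = truth["n_cell"] - cfg.n_medium
        expected = dn * truth["volume_um3"] / cfg.alpha_um3_per_pg
        assert np.allclose(truth["dry_mass_pg"], expected, rtol=1e-12)


class TestMakeWoundAssay:
    def small_spec(self, **kwargs):
        base = dict(
            field_width_um=300.0, field_height_um=60.0,
            gap_start_um=60.0, gap_end_um=240.0,
            speed_left_um_per_min=0.2, speed_right_um_per_min=0.1,
            noise_sd_rad=0.0, n_frames=6, seed=11,
        )
        base.update(kwargs)
        return AssaySpec(**base)

    def test_zero_speed_frames_identical(self, cfg):
        spec = self.small_spec(speed_left_um_per_min=0.0, speed_right_um_per_min=0.0,
                               thickness_rate_left_nm_per_min=0.0,
                               thickness_rate_right_nm_per_min=0.0)
        frames, _ = make_wound_assay(spec, cfg)
        for f in frames[1:]:
            assert np.array_equal(f.values, frames[0].values)

    def test_truth_self_consistency(self, cfg):
        frames, truth = make_wound_assay(self.small_spec(), cfg)
        t = truth.table
        # DM = dn * V / alpha holds frame-wise (single shared n_cell here)
        dn = truth.spec.n_cell_left - cfg.n_medium
        assert np.allclose(t["dry_mass_pg"], dn * t["volume_um3"] / cfg.alpha_um3_per_pg,
                           rtol=1e-12)
        assert np.allclose(t["volume_um3"],
                           t["area_in_gap_um2"] * t["d_mean_um"], rtol=1e-12)

    def test_determinism_bit_identical(self, cfg):
        spec = self.small_spec(noise_sd_rad=0.05)
        a, _ = make_wound_assay(spec, cfg)
        b, _ = make_wound_assay(spec, cfg)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))

    def test_front_collision_rejected(self, cfg):
        with pytest.raises(ValidationError, match="collide"):
            self.small_spec(speed_left_um_per_min=2.0, speed_right_um_per_min=2.0,
                            n_frames=60)

    def test_noise_free_recovery_of_area_and_mass_rates(self, cfg):
        spec = self.small_spec(n_frames=16)
        frames, truth = make_wound_assay(spec, cfg)
        geom = WoundGeometry("x", spec.gap_start_um, spec.gap_end_um)
        cov = gap_coverage_series(frames, geom)
        slope = stats.linregress(cov["time_min"], cov["S_c_um2"]).slope
        planted = (spec.speed_left_um_per_min + spec.speed_right_um_per_min) * spec.field_height_um
        assert slope == pytest.approx(planted, rel=0.02)
        # dry-mass rate via full frame metrics vs planted truth
        gap = geom.mask(frames[0].shape, cfg.pixel_pitch_um).values
        dm = [
            compute_frame_metrics(
                f, segment_cells(f).values & gap, spec.n_cell_left, cfg
            ).dry_mass_pg
            for f in frames
        ]
        slope_dm = stats.linregress(cov["time_min"], dm).slope
        truth_slope = stats.linregress(
            truth.table["time_min"], truth.table["dry_mass_pg"]
        ).slope
        assert slope_dm == pytest.approx(truth_slope, rel=0.02)

    def test_noisy_recovery_within_two_se(self, cfg):
        slopes, ses = [], []
        for seed in (1, 2, 3):
            spec = self.small_spec(noise_sd_rad=0.05, n_frames=16, seed=seed)
            frames, _ = make_wound_assay(spec, cfg)
            geom = WoundGeometry("x", spec.gap_start_um, spec.gap_end_um)
            cov = gap_coverage_series(frames, geom)
            fit = stats.linregress(cov["time_min"], cov["S_c_um2"])
            slopes.append(fit.slope)
            ses.append(fit.stderr)
        planted = 0.3 * 60.0  # (0.2 + 0.1) um/min * 60 um height
        for slope, se in zip(slopes, ses):
            assert abs(slope - planted) < 2 * max(se, 0.02 * planted)


class TestEncodeAssayHolograms:
    def test_round_trip_recovers_stack(self, cfg):
        spec = AssaySpec(
            field_width_um=120.0, field_height_um=60.0,
            gap_start_um=36.0, gap_end_um=84.0,
            speed_left_um_per_min=0.2, speed_right_um_per_min=0.0,
            noise_sd_rad=0.0, n_frames=3, seed=2,
        )
        frames, _ = make_wound_assay(spec, cfg)
        holos = encode_assay_holograms(frames, (1 / 6, 1 / 8))
        for img, holo in zip(frames, holos):
            rec = unwrap_phase(reconstruct_phase(holo, carrier_hint=(1 / 6, 1 / 8)))
            err = rec.values[8:-8, 8:-8] - img.values[8:-8, 8:-8]
            assert np.sqrt((err**2).mean()) < 0.05

    def test_seeded_noise_reproducible(self, cfg):
        frames, _ = make_wound_assay(
            AssaySpec(field_width_um=120.0, field_height_um=60.0,
                      gap_start_um=36.0, gap_end_um=84.0, n_frames=2,
                      noise_sd_rad=0.0, seed=2),
            cfg,
        )
        a = encode_assay_holograms(frames, (1 / 6, 0), noise_sd=0.1, seed=9)
        b = encode_assay_holograms(frames, (1 / 6, 0), noise_sd=0.1, seed=9)
        assert all(np.array_equal(x.intensity, y.intensity) for x, y in zip(a, b))
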