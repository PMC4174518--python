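"""Per-frame assay metrics, relative series, rate constants and profiles."""

import numpy as np
import pandas as pd
import pytest

from dhmwound import (
    FrameMetrics,
    PhaseImage,
    ValidationError,
    compute_frame_metrics,
    estimate_cell_number,
    estimate_rates,
    relative_series,
    sphere_dry_mass,
    thickness_profile,
)
from dhmwound.metrics import frames_to_table
from conftest import uniform_image


def linear_frames(slope_pg_per_min, n=81, dt=30.0):
    return [
        FrameMetrics(
            time_min=i * dt, S_c_um2=1000.0, mean_phase_rad=1.0,
            dry_mass_pg=slope_pg_per_min * i * dt, d_mean_um=5.0, volume_um3=5000.0,
        )
        for i in range(n)
    ]


class TestComputeFrameMetrics:
    def test_uniform_plateau_closed_forms(self, cfg):
        img = uniform_image(3.8148, shape=(20, 20), time_min=0.0)
        mask = np.zeros((20, 20), bool)
        mask.ravel()[:400] = True  # 100 um^2
        m = compute_frame_metrics(img, mask, 1.3713, cfg)
        assert m.S_c_um2 == pytest.approx(100.0)
        assert m.d_mean_um == pytest.approx(10.0, rel=1e-3)
        assert m.dry_mass_pg == pytest.approx(161.5, abs=0.2)
        assert m.volume_um3 == pytest.approx(1000.0, rel=1e-3)

    def test_empty_mask_gives_zero_metrics_not_error(self, cfg):
        img = uniform_image(1.0)
        m = compute_frame_metrics(img, np.zeros(img.shape, bool), 1.3713, cfg)
        assert (m.S_c_um2, m.dry_mass_pg, m.d_mean_um, m.volume_um3) == (0, 0, 0, 0)

    def test_mass_volume_identity_on_random_inputs(self, cfg):
        rng = np.random.default_rng(8)
        for _ in range(5):
            img = PhaseImage(values=rng.uniform(0, 3, (30, 30)), pixel_pitch_um=0.5)
            mask = rng.random((30, 30)) > 0.5
            m = compute_frame_metrics(img, mask, 1.3713, cfg)
            assert m.dry_mass_pg == pytest.approx(
                sphere_dry_mass(m.volume_um3, 1.3713, cfg), rel=1e-12
            )

    def test_cell_number_only_when_single_cell_mass_given(self, cfg):
        img = uniform_image(2.0)
        mask = np.ones(img.shape, bool)
        without = compute_frame_metrics(img, mask, 1.3713, cfg)
        with_dm = compute_frame_metrics(img, mask, 1.3713, cfg, dm_single_pg=265.0)
        assert without.n_cells_est is None
        assert with_dm.n_cells_est == pytest.approx(with_dm.dry_mass_pg / 265.0)


class TestRelativeSeries:
    def test_constant_series_zero_delta(self):
        frames = [
            FrameMetrics(30.0 * i, 500.0, 1.0, 800.0, 4.0, 2000.0) for i in range(5)
        ]
        df = relative_series(frames)
        assert np.allclose(df["dS_c_um2"], 0.0)
        assert np.allclose(df["dDM_pg"], 0.0)

    def test_linear_mass_accumulation_over_forty_hours(self):
        df = relative_series(linear_frames(18.3))
        # 18.3 pg/min * 2400 min
        assert df["dDM_pg"].iloc[-1] == pytest.approx(43920.0, rel=1e-12)
        assert df["dDM_pg"].iloc[0] == 0.0

    def test_unordered_times_rejected(self):
        frames = linear_frames(1.0, n=3)
        frames[1], frames[2] = frames[2], frames[1]
        with pytest.raises(ValidationError, match="time-ordered"):
            relative_series(frames)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValidationError):
            relative_series(linear_frames(1.0, n=1))


class TestEstimateCellNumber:
    def test_printed_quotient(self):
        # 23.9 ng relative mass over a 265 pg mean single cell
        assert estimate_cell_number(23900.0, 265.0) == pytest.approx(90.2, abs=0.05)

    def test_zero_mass_zero_cells(self):
        assert estimate_cell_number(0.0, 500.0) == 0.0

    def test_negative_mass_warns_but_passes_through(self):
        with pytest.warns(UserWarning, match="mass loss"):
            n = estimate_cell_number(-100.0, 200.0)
        assert n == pytest.approx(-0.5)

    def test_nonpositive_single_cell_mass_rejected(self):
        with pytest.raises(ValidationError):
            estimate_cell_number(100.0, 0.0)


class TestEstimateRates:
    def exact_line_table(self, slope=23.1, n=81, dt=30.0):
        t = np.arange(n) * dt
        return pd.DataFrame(
            {
                "time_min": t,
                "S_c_um2": 1000.0 + slope * t,
                "dry_mass_pg": 500.0 + 10.0 * t,
                "d_mean_um": 5.0 + 0.00051 * t,
                "volume_um3": 5000.0 + 111.0 * t,
            }
        )

    def test_exact_linear_input(self):
        est = estimate_rates(self.exact_line_table())
        by_metric = est.table.set_index("metric")
        assert by_metric.loc["S_c_um2", "slope"] == pytest.approx(23.1, rel=1e-9)
        assert by_metric.loc["S_c_um2", "se"] == pytest.approx(0.0, abs=1e-9)
        # thickness slope reported in nm/min
        assert by_metric.loc["d_mean_um", "units"] == "nm_per_min"
        assert by_metric.loc["d_mean_um", "slope"] == pytest.approx(0.51, rel=1e-9)

    def test_noisy_line_recovered_within_two_se(self):
        rng = np.random.default_rng(17)
        df = self.exact_line_table()
        df["S_c_um2"] += rng.normal(0, 200, len(df))
        est = estimate_rates(df, metrics=("S_c_um2",))
        row = est.table.iloc[0]
        assert abs(row["slope"] - 23.1) < 2 * row["se"]

    def test_constant_series_zero_slope(self):
        df = self.exact_line_table(slope=0.0)
        df["S_c_um2"] = 1000.0
        est = estimate_rates(df, metrics=("S_c_um2",))
        assert est.table.iloc[0]["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_replicates_averaged_before_regression(self):
        a = self.exact_line_table(slope=20.0)
        b = self.exact_line_table(slope=26.2)
        est = estimate_rates([a, b], metrics=("S_c_um2",))
        assert est.table.iloc[0]["slope"] == pytest.approx(23.1, rel=1e-9)
        assert est.n_replicates == 2

    def test_time_unit_rescaling_transforms_slope_exactly(self):
        df = self.exact_line_table()
        est_min = estimate_rates(df, metrics=("S_c_um2",))
        hours = df.copy()
        hours["time_min"] = hours["time_min"] / 60.0  # now in hours
        est_h = estimate_rates(hours, metrics=("S_c_um2",))
        assert est_h.table.iloc[0]["slope"] == pytest.approx(
            60.0 * est_min.table.iloc[0]["slope"], rel=1e-9
        )

    def test_mismatched_replicate_grids_rejected(self):
        a = self.exact_line_table()
        b = self.exact_line_table(dt=20.0)
        with pytest.raises(ValidationError, match="grid"):
            estimate_rates([a, b])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            estimate_rates(self.exact_line_table(n=2))


class TestThicknessProfile:
    def test_uniform_plateau_flat_profile(self, cfg):
        img = uniform_image(3.8148, shape=(40, 60))
        prof = thickness_profile(img, 1.3713, cfg, axis="x")
        assert np.allclose(prof["d_um"], 10.0, rtol=1e-3)

    def test_planted_wedge_linear_profile(self, cfg):
        from dhmwound import phase_from_thickness

        d = np.tile(np.linspace(0.0, 10.0, 200), (50, 1))
        img = PhaseImage(values=phase_from_thickness(d, 1.3713, cfg), pixel_pitch_um=0.5)
        prof = thickness_profile(img, 1.3713, cfg, axis="x")
        assert prof["d_um"].iloc[0] == pytest.approx(0.0, abs=0.05)
        assert prof["d_um"].iloc[-1] == pytest.approx(10.0, rel=0.02)

    def test_gap_frame_dips_to_zero(self, cfg):
        values = np.full((40, 120), 2.0)
        values[:, 40:80] = 0.0
        img = PhaseImage(values=values, pixel_pitch_um=0.5)
        prof = thickness_profile(img, 1.3713, cfg, axis="x")
        assert prof["d_um"].iloc[60] == pytest.approx(0.0, abs=1e-9)
        assert prof["d_um"].iloc[10] > 1.0

    def test_empty_band_rejected(self, cfg):
        img = uniform_image(1.0)
        with pytest.raises(ValidationError, match="empty"):
            thickness_profile(img, 1.3713, cfg, band=np.zeros(img.shape, bool))
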