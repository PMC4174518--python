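"""Time-lapse wound-assay morphometry.

Per frame: covered area S_c, mean phase over the covered region, dry
mass, mean thickness, layer volume V = S_c * d_mean, and (given a mean
single-cell dry mass) an estimated cell number n = dDM / DM_single.
Per series: changes relative to the first frame and per-minute rate
constants from ordinary least squares, optionally after averaging
replicate series on a shared time grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .optics import (
    MaskLike,
    OpticalConfig,
    PhaseImage,
    RegionMask,
    dry_mass,
    layer_volume,
    mean_thickness,
)

__all__ = [
    "FrameMetrics",
    "RateEstimates",
    "compute_frame_metrics",
    "relative_series",
    "estimate_cell_number",
    "estimate_rates",
    "thickness_profile",
]

#: metric column -> (slope unit, multiplier from per-um-units to the reported unit)
_RATE_UNITS = {
    "S_c_um2": ("um2_per_min", 1.0),
    "dry_mass_pg": ("pg_per_min", 1.0),
    "d_mean_um": ("nm_per_min", 1000.0),
    "volume_um3": ("um3_per_min", 1.0),
}


@dataclass(frozen=True)
class FrameMetrics:
    """All per-frame quantities; volume and dry mass obey DM = dn * V / alpha."""

    time_min: float
    S_c_um2: float
    mean_phase_rad: float
    dry_mass_pg: float
    d_mean_um: float
    volume_um3: float
    n_cells_est: float | None = None


@dataclass(frozen=True)
class RateEstimates:
    """OLS slopes (and their regression SEs) per metric, tidy table inside."""

    table: pd.DataFrame  # columns: metric, slope, se, units
    n_frames: int
    n_replicates: int


def compute_frame_metrics(
    img: PhaseImage,
    mask: MaskLike,
    n_cell: float,
    cfg: OpticalConfig,
    dm_single_pg: float | None = None,
) -> FrameMetrics:
    """Evaluate every frame metric over a (possibly empty) covered-region mask."""
    img.check_config(cfg)
    arr = mask.values if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    if arr.shape != img.values.shape:
        raise ValidationError("mask shape does not match the frame")
    t = img.time_min if img.time_min is not None else 0.0
    if not arr.any():
        # a frame without any covered pixels is a valid observation, not an error
        return FrameMetrics(t, 0.0, 0.0, 0.0, 0.0, 0.0,
                            0.0 if dm_single_pg is not None else None)
    s_c = float(arr.sum()) * img.pixel_pitch_um**2
    phase_mean = float(img.values[arr].mean())
    dm = dry_mass(img, arr, cfg)
    d_mean = mean_thickness(img, arr, n_cell, cfg)
    vol = layer_volume(s_c, d_mean)
    n_est = None
    if dm_single_pg is not None:
        n_est = estimate_cell_number(dm, dm_single_pg)
    return FrameMetrics(t, s_c, phase_mean, dm, d_mean, vol, n_est)


def frames_to_table(frames: list[FrameMetrics]) -> pd.DataFrame:
    rows = [
        {
            "time_min": f.time_min,
            "S_c_um2": f.S_c_um2,
            "mean_phase_rad": f.mean_phase_rad,
            "dry_mass_pg": f.dry_mass_pg,
            "d_mean_um": f.d_mean_um,
            "volume_um3": f.volume_um3,
            "n_cells_est": f.n_cells_est,
        }
        for f in frames
    ]
    return pd.DataFrame(rows)


def relative_series(frames: list[FrameMetrics]) -> pd.DataFrame:
    """Changes relative to the first frame for area and dry mass.

    Thickness and volume stay absolute.  Requires >= 2 time-ordered
    frames; the first row's deltas are exactly 0 by construction.
    """
    if len(frames) < 2:
        raise ValidationError("relative series needs at least 2 frames")
    times = np.array([f.time_min for f in frames], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("frames must be strictly time-ordered")
    df = frames_to_table(frames)
    df["dS_c_um2"] = df["S_c_um2"] - df["S_c_um2"].iloc[0]
    df["dDM_pg"] = df["dry_mass_pg"] - df["dry_mass_pg"].iloc[0]
    return df


def estimate_cell_number(delta_dm_pg: float, dm_single_mean_pg: float) -> float:
    """Cell count (fractional) as dDM over the mean single-cell dry mass."""
    if dm_single_mean_pg <= 0:
        raise ValidationError(
            f"mean single-cell dry mass must be > 0 pg, got {dm_single_mean_pg}"
        )
    if delta_dm_pg < 0:
        warnings.warn(
            "negative dry-mass change: cell-number estimate is negative (mass loss)",
            stacklevel=2,
        )
    return delta_dm_pg / dm_single_mean_pg


def estimate_rates(
    series: pd.DataFrame | list[pd.DataFrame],
    metrics: tuple[str, ...] = ("S_c_um2", "dry_mass_pg", "d_mean_um", "volume_um3"),
    time_col: str = "time_min",
) -> RateEstimates:
    """Per-minute rate constants by OLS on a series or replicate-averaged series.

    Replicates (a list of frames tables) must share the same time grid;
    their metric values are averaged per time point before the single
    regression, and thickness slopes are reported in nm/min.
    """
    if isinstance(series, pd.DataFrame):
        reps = [series]
    else:
        reps = list(series)
    if not reps:
        raise ValidationError("no series given")
    grid = reps[0][time_col].to_numpy(dtype=float)
    for i, rep in enumerate(reps[1:], start=2):
        other = rep[time_col].to_numpy(dtype=float)
        if other.shape != grid.shape or not np.allclose(other, grid):
            raise ValidationError(f"replicate {i} time grid differs from replicate 1")
    if len(grid) < 3:
        raise ValidationError("rate estimation needs at least 3 time points")
    rows = []
    for metric in metrics:
        if metric not in _RATE_UNITS:
            raise ValidationError(f"unknown rate metric {metric!r}")
        unit, scale = _RATE_UNITS[metric]
        y = np.mean([rep[metric].to_numpy(dtype=float) for rep in reps], axis=0)
        fit = stats.linregress(grid, y)
        rows.append(
            {
                "metric": metric,
                "slope": fit.slope * scale,
                "se": fit.stderr * scale,
                "units": unit,
            }
        )
    return RateEstimates(
        table=pd.DataFrame(rows), n_frames=len(grid), n_replicates=len(reps)
    )


def thickness_profile(
    img: PhaseImage,
    n_cell: float,
    cfg: OpticalConfig,
    axis: str = "x",
    band: MaskLike | None = None,
) -> pd.DataFrame:
    """Averaged thickness profile along one axis, um vs position in um.

    For axis "x" each column's phase is averaged over the band rows and
    converted to thickness; the resulting 1-D profile dips to ~0 where
    the field is cell-free (e.g. inside a wound gap).
    """
    img.check_config(cfg)
    if axis not in ("x", "y"):
        raise ValidationError(f"axis must be 'x' or 'y', got {axis!r}")
    if band is None:
        arr = np.ones(img.shape, dtype=bool)
    else:
        arr = band.values if isinstance(band, RegionMask) else np.asarray(band, bool)
        if arr.shape != img.shape:
            raise ValidationError("band mask shape does not match the frame")
    if not arr.any():
        raise ValidationError("empty band mask")
    masked = np.where(arr, img.values, np.nan)
    mean_axis = 0 if axis == "x" else 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices outside the band
        prof_phase = np.nanmean(masked, axis=mean_axis)
    n = img.shape[1] if axis == "x" else img.shape[0]
    pos = (np.arange(n) + 0.5) * img.pixel_pitch_um
    thickness = cfg.wavelength_um * prof_phase / (2.0 * np.pi * (n_cell - cfg.n_medium))
    return pd.DataFrame({f"{axis}_um": pos, "d_um": thickness}).dropna().reset_index(drop=True)
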