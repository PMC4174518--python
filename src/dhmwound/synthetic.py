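"""Synthetic test data with planted, recorded ground truth.

Two generators mirror the experimental designs the pipeline analyses:

* suspended near-spherical single cells whose radius and integral
  refractive index are drawn from a population (truncated normals), as
  when detached cells are measured one by one in suspension;
* a two-front wound assay: a cell-free band between two confluent cell
  sheets whose fronts advance linearly in time while the layers thicken
  linearly, imaged every ``frame_interval_min`` minutes.

Planted dynamics are piecewise linear because the assay metrics the
pipeline estimates are themselves rates of nearly linear time courses;
no cell-level motility model is attempted.  Every generator records its
draws so recovery tests can compare against exact planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .holography import Hologram, simulate_hologram
from .optics import OpticalConfig, PhaseImage, phase_from_thickness, pixel_grid
from .spherefit import sphere_phase_model

__all__ = [
    "SpherePopulationSpec",
    "AssaySpec",
    "AssayGroundTruth",
    "CONTROL_POPULATION",
    "EGF_POPULATION",
    "MITOMYCIN_POPULATION",
    "make_sphere_image",
    "make_sphere_population",
    "make_wound_assay",
    "encode_assay_holograms",
]


@dataclass(frozen=True)
class SpherePopulationSpec:
    """Population parameters for suspended single cells.

    Radius in um (population mean and SD), integral refractive index
    (mean and SD), additive Gaussian phase noise SD in rad.  Draws are
    truncated: radius > 1 um, index > n_medium + 0.001.
    """

    n_cells: int = 89
    radius_mean_um: float = 7.2
    radius_sd_um: float = 1.2
    n_cell_mean: float = 1.3713
    n_cell_sd: float = 0.0057
    noise_sd_rad: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.radius_mean_um <= 0 or self.radius_sd_um < 0 or self.n_cell_sd < 0:
            raise ValidationError("population means must be positive, SDs non-negative")


# Populations of the three stimulation conditions; the index SDs are the
# per-condition standard errors at n = 89 scaled back to population SDs.
CONTROL_POPULATION = SpherePopulationSpec(
    n_cells=89, radius_mean_um=7.2, radius_sd_um=1.2,
    n_cell_mean=1.3713, n_cell_sd=0.0006 * np.sqrt(89),
)
EGF_POPULATION = SpherePopulationSpec(
    n_cells=89, radius_mean_um=9.1, radius_sd_um=1.3,
    n_cell_mean=1.3707, n_cell_sd=0.0004 * np.sqrt(89),
)
MITOMYCIN_POPULATION = SpherePopulationSpec(
    n_cells=89, radius_mean_um=11.7, radius_sd_um=1.3,
    n_cell_mean=1.3678, n_cell_sd=0.0004 * np.sqrt(89),
)


@dataclass(frozen=True)
class AssaySpec:
    """Planted two-front wound assay.

    The gap band runs along x: cells cover ``x < gap_start_um`` (left
    side) and ``x >= gap_end_um`` (right side) at t = 0.  Each front
    advances into the gap at its (possibly negative) speed while its
    layer thickens at its thickness rate.  Defaults mirror a typical
    insert-based assay: 500-um initial gap, frames every 30 min for 40 h,
    and a combined front speed of 0.2 um/min, which almost closes the
    gap by the last frame.
    """

    field_width_um: float = 700.0
    field_height_um: float = 110.0
    gap_start_um: float = 100.0
    gap_end_um: float = 600.0
    speed_left_um_per_min: float = 0.1
    speed_right_um_per_min: float = 0.1
    thickness0_left_um: float = 5.0
    thickness0_right_um: float = 5.0
    thickness_rate_left_nm_per_min: float = 0.51
    thickness_rate_right_nm_per_min: float = 0.51
    n_cell_left: float = 1.3713
    n_cell_right: float = 1.3713
    frame_interval_min: float = 30.0
    n_frames: int = 81
    noise_sd_rad: float = 0.05
    front_roughness_amp_um: float = 0.0
    front_roughness_period_um: float = 27.5
    edge_softness_um: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValidationError("frame interval must be > 0 min")
        if self.n_frames < 2:
            raise ValidationError("an assay needs at least 2 frames")
        if not (0 <= self.gap_start_um < self.gap_end_um <= self.field_width_um):
            raise ValidationError("gap band must lie inside the field")
        t_end = (self.n_frames - 1) * self.frame_interval_min
        margin = abs(self.front_roughness_amp_um)
        for t in (0.0, t_end):
            left = self.gap_start_um + self.speed_left_um_per_min * t
            right = self.gap_end_um - self.speed_right_um_per_min * t
            if left + margin >= right - margin:
                raise ValidationError(
                    f"fronts collide at t = {t} min; spec invalid for this duration"
                )
            if left < 0 or right > self.field_width_um:
                raise ValidationError("a retreating front leaves the field")

    def front_positions(self, t_min: float) -> tuple[float, float]:
        return (
            self.gap_start_um + self.speed_left_um_per_min * t_min,
            self.gap_end_um - self.speed_right_um_per_min * t_min,
        )

    def thicknesses(self, t_min: float) -> tuple[float, float]:
        return (
            self.thickness0_left_um + self.thickness_rate_left_nm_per_min * t_min / 1000.0,
            self.thickness0_right_um + self.thickness_rate_right_nm_per_min * t_min / 1000.0,
        )


@dataclass(frozen=True)
class AssayGroundTruth:
    """Closed-form per-frame truth plus the generating spec echoed back.

    ``table`` columns: time_min, area_in_gap_um2, d_mean_um, volume_um3,
    dry_mass_pg — all for the cell-covered region inside the gap band,
    internally consistent with DM = dn * V / alpha by construction.
    """

    spec: AssaySpec
    table: pd.DataFrame


def make_sphere_image(
    radius_um: float,
    n_cell: float,
    cfg: OpticalConfig,
    center_um: tuple[float, float] | None = None,
    field_shape: tuple[int, int] = (128, 128),
    noise_sd_rad: float = 0.0,
    seed: int | None = None,
) -> PhaseImage:
    """Phase image of one suspended spherical cell (plus optional noise)."""
    ny, nx = field_shape
    pitch = cfg.pixel_pitch_um
    if center_um is None:
        center_um = (nx * pitch / 2.0, ny * pitch / 2.0)
    cx, cy = center_um
    if (cx - radius_um < 0 or cx + radius_um > nx * pitch
            or cy - radius_um < 0 or cy + radius_um > ny * pitch):
        raise ValidationError(
            f"sphere footprint (r = {radius_um} um at {center_um}) clipped by the "
            f"{nx * pitch} x {ny * pitch} um field"
        )
    xg, yg = pixel_grid(field_shape, pitch)
    values = sphere_phase_model(xg, yg, center_um, radius_um, n_cell, cfg)
    if noise_sd_rad > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd_rad, size=values.shape)
    return PhaseImage(values=values, pixel_pitch_um=pitch)


def _truncated_normal(rng, mean, sd, lower, size):
    """Rejection-sample a normal truncated below at ``lower``."""
    if sd == 0:
        if mean <= lower:
            raise ValidationError(f"degenerate draw: mean {mean} at or below bound {lower}")
        return np.full(size, mean, dtype=float)
    out = rng.normal(mean, sd, size=size)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= lower
    return out


def make_sphere_population(
    spec: SpherePopulationSpec,
    cfg: OpticalConfig,
    field_shape: tuple[int, int] = (128, 128),
) -> tuple[list[PhaseImage], pd.DataFrame]:
    """Draw a population of sphere images; the truth table records every draw."""
    rng = np.random.default_rng(spec.seed)
    radii = _truncated_normal(rng, spec.radius_mean_um, spec.radius_sd_um, 1.0, spec.n_cells)
    indices = _truncated_normal(
        rng, spec.n_cell_mean, spec.n_cell_sd, cfg.n_medium + 0.001, spec.n_cells
    )
    ny, nx = field_shape
    pitch = cfg.pixel_pitch_um
    center = (nx * pitch / 2.0, ny * pitch / 2.0)
    images, rows = [], []
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_cells)
    for i in range(spec.n_cells):
        noise_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
        img = make_sphere_image(
            float(radii[i]), float(indices[i]), cfg,
            center_um=center, field_shape=field_shape,
            noise_sd_rad=spec.noise_sd_rad, seed=noise_seed,
        )
        images.append(img)
        vol = 4.0 / 3.0 * np.pi * radii[i] ** 3
        rows.append(
            {
                "cell": i,
                "radius_um": float(radii[i]),
                "n_cell": float(indices[i]),
                "volume_um3": float(vol),
                "dry_mass_pg": float((indices[i] - cfg.n_medium) * vol / cfg.alpha_um3_per_pg),
            }
        )
    return images, pd.DataFrame(rows)


def make_wound_assay(
    spec: AssaySpec, cfg: OpticalConfig
) -> tuple[list[PhaseImage], AssayGroundTruth]:
    """Render the planted assay to phase frames and closed-form truth.

    A front is a linear phase ramp of width ``edge_softness_um`` centred
    on the front line (an epithelial sheet tapers toward its migration
    front over a few micrometres rather than ending in a vertical wall); the ramp is symmetric, so the closed-form area, volume and
    dry-mass truths based on the front-line position are exact.  With
    roughness enabled the front line is additionally perturbed
    sinusoidally along y (zero mean, so closed-form truths again use the
    base positions).
    """
    pitch = cfg.pixel_pitch_um
    nx = int(round(spec.field_width_um / pitch))
    ny = int(round(spec.field_height_um / pitch))
    xg, yg = pixel_grid((ny, nx), pitch)
    rng = np.random.default_rng(spec.seed)
    rough_phase = rng.uniform(0, 2 * np.pi, size=2)  # per-side phase of the sinusoid
    frames: list[PhaseImage] = []
    rows = []
    for k in range(spec.n_frames):
        t = k * spec.frame_interval_min
        left, right = spec.front_positions(t)
        d_left, d_right = spec.thicknesses(t)
        wobble_l = wobble_r = 0.0
        if spec.front_roughness_amp_um:
            wobble_l = spec.front_roughness_amp_um * np.sin(
                2 * np.pi * yg[:, :1] / spec.front_roughness_period_um + rough_phase[0]
            )
            wobble_r = spec.front_roughness_amp_um * np.sin(
                2 * np.pi * yg[:, :1] / spec.front_roughness_period_um + rough_phase[1]
            )
        soft = spec.edge_softness_um
        if soft > 0:
            occ_left = np.clip((left + wobble_l - xg) / soft + 0.5, 0.0, 1.0)
            occ_right = np.clip((xg - (right - wobble_r)) / soft + 0.5, 0.0, 1.0)
        else:
            occ_left = (xg < left + wobble_l).astype(float)
            occ_right = (xg >= right - wobble_r).astype(float)
        values = (
            occ_left * phase_from_thickness(d_left, spec.n_cell_left, cfg)
            + occ_right * phase_from_thickness(d_right, spec.n_cell_right, cfg)
        )
        if spec.noise_sd_rad > 0:
            values = values + rng.normal(0.0, spec.noise_sd_rad, size=values.shape)
        frames.append(PhaseImage(values=values, pixel_pitch_um=pitch, time_min=t))

        h = spec.field_height_um
        area_l = max(left - spec.gap_start_um, 0.0) * h
        area_r = max(spec.gap_end_um - right, 0.0) * h
        area = area_l + area_r
        vol = area_l * d_left + area_r * d_right
        d_mean = vol / area if area > 0 else 0.0
        dm = (
            (spec.n_cell_left - cfg.n_medium) * area_l * d_left
            + (spec.n_cell_right - cfg.n_medium) * area_r * d_right
        ) / cfg.alpha_um3_per_pg
        rows.append(
            {
                "time_min": t,
                "area_in_gap_um2": area,
                "d_mean_um": d_mean,
                "volume_um3": vol,
                "dry_mass_pg": dm,
            }
        )
    truth = AssayGroundTruth(spec=spec, table=pd.DataFrame(rows))
    return frames, truth


def encode_assay_holograms(
    stack: list[PhaseImage],
    carrier: tuple[float, float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    **hologram_kwargs,
) -> list[Hologram]:
    """Render every phase frame to an off-axis hologram (seeded per frame)."""
    child = np.random.SeedSequence(seed).spawn(len(stack))
    return [
        simulate_hologram(
            img, carrier, noise_sd=noise_sd,
            seed=int(child[i].generate_state(1)[0] % (2**31)),
            **hologram_kwargs,
        )
        for i, img in enumerate(stack)
    ]
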