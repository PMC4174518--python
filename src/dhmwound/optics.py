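"""Governing optics relations of quantitative phase imaging.

A transparent cell of thickness ``d`` and integral refractive index
``n_cell`` immersed in a medium of index ``n_medium`` delays the object
wave and produces a phase contrast

    delta_phi = (2 pi / lambda) * (n_cell - n_medium) * d .

Two derived quantities drive all downstream morphometry:

* dry mass ``DM = lambda / (2 pi alpha) * sum_i delta_phi_i * A_pixel``,
  where ``alpha`` is the refractive increment of cellular dry matter
  (how much the refractive index rises per unit mass concentration);
* mean thickness ``d_mean = lambda * mean(delta_phi) / (2 pi * (n_cell -
  n_medium))``, the exact inverse of the phase relation.

Internal unit system: micrometres for lengths, radians for phase,
picograms for mass, minutes for time.  All conversions are centralised in
:class:`OpticalConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Union

import numpy as np

from .errors import ValidationError

__all__ = [
    "OpticalConfig",
    "PhaseImage",
    "RegionMask",
    "phase_from_thickness",
    "mean_thickness",
    "dry_mass",
    "sphere_dry_mass",
    "layer_volume",
    "pixel_grid",
]

# 1 m^3/kg == 1e18 um^3 / 1e15 pg
_M3_PER_KG_TO_UM3_PER_PG = 1.0e3


@dataclass(frozen=True)
class OpticalConfig:
    """Optical configuration shared by every quantitative operation.

    Parameters
    ----------
    wavelength_nm
        Vacuum wavelength of the laser, nanometres (default 532, a
        frequency-doubled Nd:YAG line).
    n_medium
        Refractive index of the culture medium (default 1.339).
    alpha_m3_per_kg
        Refractive increment of cellular dry matter, m^3/kg.  Default
        2e-4 (equivalently 0.2 mL/g), the standard protein value.
    pixel_pitch_um
        Pixel pitch in object space (camera pitch divided by lateral
        magnification), micrometres.
    """

    wavelength_nm: float = 532.0
    n_medium: float = 1.339
    alpha_m3_per_kg: float = 2.0e-4
    pixel_pitch_um: float = 0.5

    def __post_init__(self) -> None:
        if not (self.wavelength_nm > 0):
            raise ValidationError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")
        if not (1.0 < self.n_medium < 1.5):
            raise ValidationError(
                f"n_medium must lie in (1.0, 1.5) for aqueous media, got {self.n_medium}"
            )
        if not (self.alpha_m3_per_kg > 0):
            raise ValidationError(
                f"alpha_m3_per_kg (refractive increment) must be > 0, got {self.alpha_m3_per_kg}"
            )
        if not (self.pixel_pitch_um > 0):
            raise ValidationError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1.0e-3

    @property
    def alpha_um3_per_pg(self) -> float:
        """Refractive increment in um^3/pg (2e-4 m^3/kg -> 0.2 um^3/pg)."""
        return self.alpha_m3_per_kg * _M3_PER_KG_TO_UM3_PER_PG

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown OpticalConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PhaseImage:
    """A 2-D quantitative phase map in radians.

    ``time_min`` is minutes since assay start; ``None`` for single shots.
    """

    values: np.ndarray
    pixel_pitch_um: float
    time_min: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"phase image must be 2-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("phase image contains non-finite values")
        if not (self.pixel_pitch_um > 0):
            raise ValidationError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def check_config(self, cfg: OpticalConfig) -> None:
        """The image pitch must match the config used for quantification."""
        if not np.isclose(self.pixel_pitch_um, cfg.pixel_pitch_um, rtol=1e-9):
            raise ValidationError(
                f"pixel pitch mismatch: image {self.pixel_pitch_um} um vs "
                f"config {cfg.pixel_pitch_um} um"
            )


@dataclass
class RegionMask:
    """Boolean mask congruent with a phase image, with physical area."""

    values: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {self.values.shape}")
        if not (self.pixel_pitch_um > 0):
            raise ValidationError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}")

    @property
    def area_um2(self) -> float:
        return float(self.values.sum()) * self.pixel_pitch_um**2

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


MaskLike = Union[RegionMask, np.ndarray]


def _mask_array(mask: MaskLike, img: PhaseImage) -> np.ndarray:
    arr = mask.values if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)
    if arr.shape != img.values.shape:
        raise ValidationError(
            f"mask shape {arr.shape} does not match image shape {img.values.shape}"
        )
    return arr


def pixel_grid(shape: tuple[int, int], pixel_pitch_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of pixel centres, micrometres.

    Row index maps to y, column index to x; pixel (0, 0) is centred at
    (pitch/2, pitch/2).
    """
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pixel_pitch_um
    y = (np.arange(ny) + 0.5) * pixel_pitch_um
    return np.meshgrid(x, y)


def phase_from_thickness(d_um, n_cell: float, cfg: OpticalConfig):
    """Phase contrast of a cell of thickness ``d_um`` (scalar or array), radians.

    delta_phi = (2 pi / lambda) (n_cell - n_medium) d
    """
    d = np.asarray(d_um, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValidationError("thickness d must be finite (micrometres)")
    if np.any(d < 0):
        raise ValidationError("thickness d must be >= 0 micrometres (negative optical "
                              "thickness has no physical meaning here)")
    if n_cell < cfg.n_medium:
        raise ValidationError(
            f"n_cell ({n_cell}) < n_medium ({cfg.n_medium}): cells are assumed "
            "optically denser than the medium"
        )
    out = 2.0 * np.pi * (n_cell - cfg.n_medium) * d / cfg.wavelength_um
    return float(out) if np.isscalar(d_um) else out


def mean_thickness(img: PhaseImage, mask: MaskLike, n_cell: float, cfg: OpticalConfig) -> float:
    """Mean cell thickness over a mask, micrometres (inverse phase relation)."""
    img.check_config(cfg)
    m = _mask_array(mask, img)
    if not m.any():
        raise ValidationError("mean_thickness: empty mask")
    if n_cell <= cfg.n_medium:
        raise ValidationError(
            f"degenerate contrast: n_cell ({n_cell}) must exceed n_medium ({cfg.n_medium})"
        )
    mean_phase = float(img.values[m].mean())
    return cfg.wavelength_um * mean_phase / (2.0 * np.pi * (n_cell - cfg.n_medium))


def dry_mass(img: PhaseImage, mask: MaskLike, cfg: OpticalConfig) -> float:
    """Dry mass over a mask, picograms.

    DM = lambda/(2 pi alpha) * sum(phase) * pixel_area; additive over
    disjoint masks by linearity of the sum.
    """
    img.check_config(cfg)
    m = _mask_array(mask, img)
    pixel_area = cfg.pixel_pitch_um**2
    phase_sum = float(img.values[m].sum())
    return cfg.wavelength_um / (2.0 * np.pi * cfg.alpha_um3_per_pg) * phase_sum * pixel_area


def sphere_dry_mass(volume_um3: float, n_cell: float, cfg: OpticalConfig) -> float:
    """Dry mass of a homogeneous cell from its volume: DM = (n_cell - n_medium) V / alpha."""
    if volume_um3 < 0:
        raise ValidationError(f"volume must be >= 0 um^3, got {volume_um3}")
    return (n_cell - cfg.n_medium) * volume_um3 / cfg.alpha_um3_per_pg


def layer_volume(area_um2: float, d_mean_um: float) -> float:
    """Cell-layer volume as covered area times mean thickness, um^3."""
    if area_um2 < 0 or d_mean_um < 0:
        raise ValidationError("area and mean thickness must both be >= 0")
    return area_um2 * d_mean_um
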