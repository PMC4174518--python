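"""Refractive index, volume and dry mass of suspended near-spherical cells.

A detached cell in suspension rounds up; along the optical axis its
geometric thickness at lateral distance ``rho`` from the centre is
``d(rho) = 2 sqrt(r^2 - rho^2)``, so the phase relation predicts

    delta_phi(rho) = (4 pi / lambda) (n_cell - n_medium) sqrt(r^2 - rho^2)

inside the footprint and 0 outside, peaking at (4 pi / lambda) dn r in
the centre.  Fitting this model to a measured phase image by nonlinear
least squares over (centre, radius, n_cell) decouples the refractive
index from the thickness: the footprint pins the radius, the amplitude
pins n_cell.  Volume and dry mass follow in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import FitConvergenceError, NoBlobError
from .optics import OpticalConfig, PhaseImage, sphere_dry_mass

__all__ = [
    "SphereFitResult",
    "PopulationSummary",
    "sphere_phase_model",
    "fit_sphere",
    "batch_fit",
]

logger = logging.getLogger(__name__)

_PARAM_COLUMNS = ("radius_um", "n_cell", "volume_um3", "dry_mass_pg")


@dataclass(frozen=True)
class SphereFitResult:
    """Fitted parameters of one suspended cell.

    ``volume_um3`` and ``dry_mass_pg`` are exact functions of the fitted
    radius and index: V = 4/3 pi r^3, DM = (n_cell - n_medium) V / alpha.
    """

    center_um: tuple[float, float]
    radius_um: float
    n_cell: float
    volume_um3: float
    dry_mass_pg: float
    rmse_rad: float
    n_pixels_fit: int


@dataclass(frozen=True)
class PopulationSummary:
    """Mean and standard error per fitted parameter over a cell population."""

    n_cells: int
    n_failed: int
    mean: dict[str, float]
    se: dict[str, float]


def sphere_phase_model(
    x_um: np.ndarray,
    y_um: np.ndarray,
    center_um: tuple[float, float],
    radius_um: float,
    n_cell: float,
    cfg: OpticalConfig,
) -> np.ndarray:
    """Phase of a homogeneous sphere evaluated at physical coordinates (um)."""
    cx, cy = center_um
    rho2 = (np.asarray(x_um) - cx) ** 2 + (np.asarray(y_um) - cy) ** 2
    chord = 2.0 * np.sqrt(np.clip(radius_um**2 - rho2, 0.0, None))
    return 2.0 * np.pi * (n_cell - cfg.n_medium) * chord / cfg.wavelength_um


def _find_blob(values: np.ndarray, threshold: float) -> np.ndarray:
    """Largest connected component above threshold, or raise NoBlobError."""
    if float(values.max()) < threshold:
        raise NoBlobError(
            f"max phase {values.max():.3f} rad below blob threshold {threshold} rad"
        )
    labels, n = ndimage.label(values > threshold)
    if n == 0:
        raise NoBlobError("no connected region above threshold")
    sizes = ndimage.sum_labels(np.ones_like(values), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _initial_guess(
    img: PhaseImage, blob: np.ndarray, cfg: OpticalConfig
) -> tuple[float, float, float, float]:
    """Deterministic initialisation: centroid, equivalent-area radius, peak index."""
    pitch = img.pixel_pitch_um
    yy, xx = np.nonzero(blob)
    w = img.values[blob]
    cx = float(((xx + 0.5) * pitch * w).sum() / w.sum())
    cy = float(((yy + 0.5) * pitch * w).sum() / w.sum())
    r0 = float(np.sqrt(blob.sum() * pitch**2 / np.pi))
    peak = float(img.values[blob].max())
    n0 = cfg.n_medium + cfg.wavelength_um * peak / (4.0 * np.pi * r0)
    return cx, cy, r0, n0


def fit_sphere(
    img: PhaseImage,
    cfg: OpticalConfig,
    init: Sequence[float] | None = None,
    blob_threshold: float = 0.5,
    window_dilation: float = 0.25,
) -> SphereFitResult:
    """Least-squares fit of the spherical-cell model to one phase image.

    The fitting window is the blob bounding box dilated by
    ``window_dilation`` on each side; background pixels inside the window
    anchor the model's zero level.
    """
    img.check_config(cfg)
    pitch = img.pixel_pitch_um
    blob = _find_blob(ndimage.gaussian_filter(img.values, 1.0), blob_threshold)
    p0 = tuple(init) if init is not None else _initial_guess(img, blob, cfg)

    yy, xx = np.nonzero(blob)
    pad_y = int(np.ceil(window_dilation * (yy.max() - yy.min() + 1)))
    pad_x = int(np.ceil(window_dilation * (xx.max() - xx.min() + 1)))
    y0, y1 = max(yy.min() - pad_y, 0), min(yy.max() + pad_y + 1, img.shape[0])
    x0, x1 = max(xx.min() - pad_x, 0), min(xx.max() + pad_x + 1, img.shape[1])
    window = img.values[y0:y1, x0:x1]
    xs = (np.arange(x0, x1) + 0.5) * pitch
    ys = (np.arange(y0, y1) + 0.5) * pitch
    xg, yg = np.meshgrid(xs, ys)

    def residuals(p: np.ndarray) -> np.ndarray:
        cx, cy, r, n = p
        return (sphere_phase_model(xg, yg, (cx, cy), r, n, cfg) - window).ravel()

    field_x = img.shape[1] * pitch
    field_y = img.shape[0] * pitch
    sol = optimize.least_squares(
        residuals,
        x0=np.asarray(p0, dtype=float),
        bounds=(
            [0.0, 0.0, 0.1, cfg.n_medium + 1e-6],
            [field_x, field_y, max(field_x, field_y), 1.5],
        ),
        x_scale=[1.0, 1.0, 1.0, 1e-3],
        method="trf",
    )
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    if not sol.success:
        raise FitConvergenceError(
            f"least squares did not converge (status {sol.status}, rmse {rmse:.4f} rad)",
            rmse=rmse,
        )
    cx, cy, r, n = (float(v) for v in sol.x)
    volume = 4.0 / 3.0 * np.pi * r**3
    return SphereFitResult(
        center_um=(cx, cy),
        radius_um=r,
        n_cell=n,
        volume_um3=volume,
        dry_mass_pg=sphere_dry_mass(volume, n, cfg),
        rmse_rad=rmse,
        n_pixels_fit=int(window.size),
    )


def batch_fit(
    images: Iterable[PhaseImage],
    cfg: OpticalConfig,
    blob_threshold: float = 0.5,
) -> tuple[PopulationSummary, pd.DataFrame]:
    """Fit every image of a stack; summarise successes as mean +/- SE.

    Failed fits (no blob, non-convergence) are logged, recorded with NaN
    rows, and excluded from the summary.  SE = SD / sqrt(n); for a single
    successful fit the SE is reported as 0 and flagged in the log.
    """
    rows = []
    n_failed = 0
    for i, img in enumerate(images):
        try:
            res = fit_sphere(img, cfg, blob_threshold=blob_threshold)
            rows.append(
                {
                    "cell": i,
                    "center_x_um": res.center_um[0],
                    "center_y_um": res.center_um[1],
                    "radius_um": res.radius_um,
                    "n_cell": res.n_cell,
                    "volume_um3": res.volume_um3,
                    "dry_mass_pg": res.dry_mass_pg,
                    "rmse_rad": res.rmse_rad,
                    "ok": True,
                }
            )
        except (NoBlobError, FitConvergenceError) as exc:
            n_failed += 1
            logger.warning("cell %d: fit failed (%s)", i, exc)
            rows.append({"cell": i, "ok": False})
    table = pd.DataFrame(rows)
    good = table[table["ok"] == True]  # noqa: E712
    if good.empty:
        raise FitConvergenceError("all sphere fits failed")
    n = len(good)
    if n == 1:
        logger.warning("population of a single cell: standard errors undefined, reported as 0")
    mean = {c: float(good[c].mean()) for c in _PARAM_COLUMNS}
    se = {c: float(good[c].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0 for c in _PARAM_COLUMNS}
    return PopulationSummary(n_cells=n, n_failed=n_failed, mean=mean, se=se), table
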