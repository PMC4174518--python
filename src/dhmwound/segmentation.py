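"""Cell-covered area from background-corrected phase images.

The covered area S_c is the physical area of pixels whose phase rises
above a threshold, after light smoothing and morphological cleanup.  The
default threshold is Otsu's value on the non-negative phase histogram
with a floor of three robust (MAD-based) noise standard deviations, so
an empty, noisy frame yields an empty mask rather than a noise mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology

from .errors import ValidationError
from .optics import MaskLike, PhaseImage, RegionMask

__all__ = [
    "WoundGeometry",
    "segment_cells",
    "gap_coverage_series",
    "label_cells",
]


@dataclass(frozen=True)
class WoundGeometry:
    """Axis-aligned band describing the initial cell-free gap.

    ``axis`` names the coordinate along which the band extends its limits:
    axis "x" means the gap spans ``gap_start_um <= x < gap_end_um`` (full
    height), axis "y" the analogue in y.  The geometry is fixed over the
    whole time series.
    """

    axis: str
    gap_start_um: float
    gap_end_um: float

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValidationError(f"geometry axis must be 'x' or 'y', got {self.axis!r}")
        if not (self.gap_end_um > self.gap_start_um):
            raise ValidationError(
                f"degenerate gap band: [{self.gap_start_um}, {self.gap_end_um}) um"
            )

    def mask(self, shape: tuple[int, int], pixel_pitch_um: float) -> RegionMask:
        """Rasterise the band: pixels whose centre lies inside it."""
        ny, nx = shape
        if self.axis == "x":
            coord = (np.arange(nx) + 0.5) * pixel_pitch_um
            inside = (coord >= self.gap_start_um) & (coord < self.gap_end_um)
            values = np.broadcast_to(inside[None, :], (ny, nx))
        else:
            coord = (np.arange(ny) + 0.5) * pixel_pitch_um
            inside = (coord >= self.gap_start_um) & (coord < self.gap_end_um)
            values = np.broadcast_to(inside[:, None], (ny, nx))
        return RegionMask(values=values.copy(), pixel_pitch_um=pixel_pitch_um)


def _drop_small_components(mask: np.ndarray, min_px: int, keep_border: bool = False) -> np.ndarray:
    """Remove connected components with fewer than ``min_px`` pixels.

    With ``keep_border`` components touching the image edge survive
    regardless of size (used to avoid filling the open background as a
    'hole').
    """
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(mask, dtype=float), labels, np.arange(1, n + 1))
    keep = sizes >= min_px
    if keep_border:
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        keep[border[border > 0] - 1] = True
    return np.isin(labels, np.nonzero(keep)[0] + 1)


def _auto_threshold(smoothed: np.ndarray) -> float:
    """Otsu on the phase histogram clipped at 0, floored at 3x the robust noise SD."""
    clipped = np.clip(smoothed, 0.0, None)
    if float(clipped.max()) <= 1e-9:
        return np.inf  # nothing above background anywhere
    otsu = float(filters.threshold_otsu(clipped))
    background = smoothed[smoothed <= otsu]
    mad = float(np.median(np.abs(background - np.median(background))))
    noise_sd = 1.4826 * mad
    return max(otsu, 3.0 * noise_sd)


def segment_cells(
    img: PhaseImage,
    threshold: float | str = "auto",
    smooth_sigma: float = 1.0,
    closing_radius_px: int = 3,
    min_object_um2: float = 50.0,
    min_hole_um2: float = 50.0,
) -> RegionMask:
    """Mask of cell-covered pixels in a background-corrected phase image.

    An empty mask is a valid result (e.g. a frame showing only the gap).
    """
    smoothed = ndimage.gaussian_filter(img.values, smooth_sigma) if smooth_sigma > 0 else img.values
    thr = _auto_threshold(smoothed) if threshold == "auto" else float(threshold)
    mask = smoothed > thr
    if mask.any():
        if closing_radius_px > 0:
            # dilate treating the outside as background, erode treating it as
            # foreground, so regions touching the image border keep their rim
            footprint = morphology.disk(closing_radius_px)
            mask = ndimage.binary_erosion(
                ndimage.binary_dilation(mask, structure=footprint, border_value=0),
                structure=footprint, border_value=1,
            )
        min_px = int(np.ceil(min_object_um2 / img.pixel_pitch_um**2))
        hole_px = int(np.ceil(min_hole_um2 / img.pixel_pitch_um**2))
        if min_px > 1:
            mask = _drop_small_components(mask, min_px)
        if hole_px > 1:
            mask = ~_drop_small_components(~mask, hole_px, keep_border=True)
    return RegionMask(values=mask, pixel_pitch_um=img.pixel_pitch_um)


def gap_coverage_series(
    stack: list[PhaseImage],
    geometry: WoundGeometry,
    threshold: float | str = "auto",
    **segment_kwargs,
) -> pd.DataFrame:
    """Per-frame covered area inside the wound gap and its change from frame 0.

    Pure bookkeeping: no temporal smoothing; dS_c(0) = 0 by construction.
    Columns: ``time_min``, ``S_c_um2``, ``dS_c_um2``.
    """
    if not stack:
        raise ValidationError("empty image stack")
    shape = stack[0].shape
    for i, img in enumerate(stack):
        if img.shape != shape:
            raise ValidationError(f"frame {i} shape {img.shape} differs from frame 0 {shape}")
    gap = geometry.mask(shape, stack[0].pixel_pitch_um).values
    rows = []
    for i, img in enumerate(stack):
        mask = segment_cells(img, threshold=threshold, **segment_kwargs).values
        area = float((mask & gap).sum()) * img.pixel_pitch_um**2
        t = img.time_min if img.time_min is not None else float(i)
        rows.append({"time_min": t, "S_c_um2": area})
    df = pd.DataFrame(rows)
    df["dS_c_um2"] = df["S_c_um2"] - df["S_c_um2"].iloc[0]
    return df


def label_cells(
    mask: MaskLike,
    min_area_um2: float = 50.0,
    pixel_pitch_um: float | None = None,
) -> tuple[np.ndarray, int]:
    """Connected-component labelling of a cell mask (best effort).

    Touching cells merge into one label; no watershed splitting is
    attempted.  Returns (label image, number of labels).
    """
    if isinstance(mask, RegionMask):
        arr, pitch = mask.values, mask.pixel_pitch_um
    else:
        if pixel_pitch_um is None:
            raise ValidationError("pixel_pitch_um required when passing a bare array")
        arr, pitch = np.asarray(mask, bool), pixel_pitch_um
    min_px = int(np.ceil(min_area_um2 / pitch**2))
    cleaned = _drop_small_components(arr, max(min_px, 1))
    labels, n = ndimage.label(cleaned)
    return labels, int(n)
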