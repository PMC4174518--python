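"""Off-axis hologram simulation and phase reconstruction.

In off-axis geometry the tilted reference wave imprints a spatial carrier
fringe on the interferogram,

    I = |O|^2 + |R|^2 + 2|O||R| cos(2 pi (fx x + fy y) + delta_phi),

which shifts the object information to a sideband at the carrier
frequency.  Reconstruction demodulates that sideband: multiply by the
conjugate carrier, low-pass filter around the origin with a raised-cosine
window, and take the argument of the resulting complex field.  The
wrapped phase is then unwrapped and a low-order polynomial background
(tilt, residual aberration) is removed using a cell-free region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import restoration

from .errors import CarrierError, ValidationError
from .optics import MaskLike, PhaseImage, RegionMask

__all__ = [
    "Hologram",
    "simulate_hologram",
    "reconstruct_phase",
    "unwrap_phase",
    "background_correct",
]


@dataclass
class Hologram:
    """Recorded off-axis interferogram.

    ``carrier`` is the fringe spatial frequency (fx, fy) in cycles/pixel;
    both components must sit strictly inside the Nyquist band so the
    sidebands do not alias.
    """

    intensity: np.ndarray
    carrier: tuple[float, float]
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValidationError(f"hologram must be 2-D, got shape {self.intensity.shape}")
        if np.any(self.intensity < 0):
            raise ValidationError("hologram intensity must be non-negative")
        _check_carrier(self.carrier)


def _check_carrier(carrier: tuple[float, float]) -> None:
    fx, fy = carrier
    mag = float(np.hypot(fx, fy))
    if mag == 0:
        raise ValidationError("carrier frequency must be non-zero (off-axis geometry)")
    if abs(fx) >= 0.5 or abs(fy) >= 0.5:
        raise ValidationError(
            f"carrier {carrier} at or beyond Nyquist (0.5 cycles/pixel): sidebands would alias"
        )


def simulate_hologram(
    phase: PhaseImage,
    carrier: tuple[float, float],
    object_amp: float | np.ndarray = 1.0,
    ref_amp: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    quantize_bits: int | None = None,
) -> Hologram:
    """Simulate the camera image of an off-axis interferogram.

    ``object_amp`` may be a scalar or a 2-D amplitude map; ``ref_amp=0``
    degenerates to a fringeless ``|O|^2`` image (still a valid Hologram
    object but not reconstructible).  ``quantize_bits`` emulates camera
    digitisation by scaling the full range onto 2**bits levels.
    """
    if ref_amp > 0:
        _check_carrier(carrier)
    ny, nx = phase.values.shape
    o = np.broadcast_to(np.asarray(object_amp, dtype=float), (ny, nx))
    if np.any(o < 0) or ref_amp < 0:
        raise ValidationError("wave amplitudes must be >= 0")
    x = np.arange(nx)[None, :]
    y = np.arange(ny)[:, None]
    fx, fy = carrier
    fringe = np.cos(2.0 * np.pi * (fx * x + fy * y) + phase.values)
    intensity = o**2 + ref_amp**2 + 2.0 * o * ref_amp * fringe
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    if quantize_bits is not None:
        levels = 2**quantize_bits - 1
        top = intensity.max()
        if top > 0:
            intensity = np.round(intensity / top * levels) / levels * top
    return Hologram(intensity=intensity, carrier=carrier, pixel_pitch_um=phase.pixel_pitch_um)


def detect_carrier(
    intensity: np.ndarray,
    dc_exclusion: float = 1.0 / 16.0,
    prominence: float = 5.0,
) -> tuple[float, float]:
    """Locate the off-origin carrier peak in the spectrum, cycles/pixel.

    Raises :class:`CarrierError` when no off-origin peak rises at least
    ``prominence`` times above the median spectral magnitude.
    """
    spec = np.fft.fft2(intensity - intensity.mean())
    mag = np.abs(np.fft.fftshift(spec))
    ny, nx = intensity.shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :]
    off_origin = np.hypot(fx, fy) > dc_exclusion
    # the spectrum is Hermitian; resolve the +/- carrier ambiguity by
    # convention: take the peak in the fx > 0 half-plane
    half = (fx > 0) | ((fx == 0) & (fy > 0))
    searchable = off_origin & half
    if not searchable.any():
        raise CarrierError("image too small to search for a carrier peak")
    floor = float(np.median(mag[off_origin]))
    search = np.where(searchable, mag, 0.0)
    iy, ix = np.unravel_index(np.argmax(search), search.shape)
    peak = float(search[iy, ix])
    if peak <= 0 or (floor > 0 and peak < prominence * floor):
        raise CarrierError(
            f"no off-origin spectral peak above {prominence}x the median magnitude "
            "(fringes absent or unresolvable)"
        )

    def _parabolic(m_minus: float, m0: float, m_plus: float) -> float:
        denom = m_minus - 2.0 * m0 + m_plus
        return 0.0 if denom == 0 else 0.5 * (m_minus - m_plus) / denom

    # sub-bin refinement: a carrier off the FFT grid would otherwise leave
    # a residual tilt of up to half a fringe across the field
    dx = dy = 0.0
    if 0 < ix < nx - 1:
        dx = _parabolic(mag[iy, ix - 1], mag[iy, ix], mag[iy, ix + 1])
    if 0 < iy < ny - 1:
        dy = _parabolic(mag[iy - 1, ix], mag[iy, ix], mag[iy + 1, ix])
    return float(fx[0, ix] + dx / nx), float(fy[iy, 0] + dy / ny)


def _raised_cosine_lowpass(shape: tuple[int, int], radius: float) -> np.ndarray:
    """Raised-cosine window around zero frequency, cutoff ``radius`` cycles/px."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    r = np.hypot(fx, fy)
    w = 0.5 * (1.0 + np.cos(np.pi * r / radius))
    return np.where(r <= radius, w, 0.0)


def reconstruct_phase(
    holo: Hologram,
    carrier_hint: tuple[float, float] | None = None,
    window_radius: float | None = None,
    prominence: float = 5.0,
) -> PhaseImage:
    """Recover the wrapped phase from an off-axis hologram.

    The hologram is multiplied by the conjugate carrier, which brings one
    cross-term sideband to the origin; a raised-cosine low-pass of radius
    ``window_radius`` (default: 0.8 times the carrier magnitude,
    cycles/pixel) isolates it, and the argument of the filtered complex
    field is the wrapped phase in (-pi, pi].  The window must stay clear
    of the autocorrelation term, which for flat-amplitude objects is a
    spectral delta sitting exactly one carrier magnitude away.
    """
    if carrier_hint is not None:
        fx, fy = carrier_hint
        _check_carrier((fx, fy))
    else:
        fx, fy = detect_carrier(holo.intensity, prominence=prominence)
    ny, nx = holo.intensity.shape
    x = np.arange(nx)[None, :]
    y = np.arange(ny)[:, None]
    demod = holo.intensity * np.exp(-2.0j * np.pi * (fx * x + fy * y))
    radius = window_radius if window_radius is not None else 0.8 * float(np.hypot(fx, fy))
    if radius <= 0:
        raise ValidationError(f"window radius must be > 0, got {radius}")
    field = np.fft.ifft2(np.fft.fft2(demod) * _raised_cosine_lowpass((ny, nx), radius))
    return PhaseImage(values=np.angle(field), pixel_pitch_um=holo.pixel_pitch_um)


def unwrap_phase(wrapped: PhaseImage, background: MaskLike | None = None) -> PhaseImage:
    """Unwrap a (-pi, pi] phase map into a continuous field.

    Uses reliability-ordered 2-D unwrapping, then shifts the minimum over
    ``background`` (default: the whole image) to zero so cell-free pixels
    sit at phase 0.
    """
    unwrapped = restoration.unwrap_phase(wrapped.values)
    unwrapped = np.asarray(unwrapped, dtype=float)
    if background is not None:
        bg = background.values if isinstance(background, RegionMask) else np.asarray(background, bool)
        if bg.shape != unwrapped.shape or not bg.any():
            raise ValidationError("background mask must be non-empty and congruent")
        offset = unwrapped[bg].min()
    else:
        offset = unwrapped.min()
    return PhaseImage(
        values=unwrapped - offset,
        pixel_pitch_um=wrapped.pixel_pitch_um,
        time_min=wrapped.time_min,
    )


def background_correct(
    phase: PhaseImage,
    cellfree: MaskLike,
    poly_order: int = 1,
) -> PhaseImage:
    """Remove a least-squares 2-D polynomial background fitted on cell-free pixels.

    Compensates reference tilt and low-order aberrations so the cell-free
    level sits at 0, a precondition of dry-mass and thickness retrieval.
    """
    mask = cellfree.values if isinstance(cellfree, RegionMask) else np.asarray(cellfree, bool)
    if mask.shape != phase.values.shape:
        raise ValidationError("cell-free mask shape does not match the phase image")
    n_terms = (poly_order + 1) * (poly_order + 2) // 2
    if mask.sum() < n_terms:
        raise ValidationError(
            f"cell-free mask has {int(mask.sum())} pixels, fewer than the {n_terms} "
            f"degrees of freedom of an order-{poly_order} polynomial"
        )
    ny, nx = phase.values.shape
    # normalized coordinates keep the Vandermonde well conditioned
    xn = (np.arange(nx) - nx / 2) / max(nx, 1)
    yn = (np.arange(ny) - ny / 2) / max(ny, 1)
    xg, yg = np.meshgrid(xn, yn)
    cols = [
        (xg**i * yg**j).ravel()
        for i in range(poly_order + 1)
        for j in range(poly_order + 1 - i)
    ]
    a = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(a[mask.ravel()], phase.values[mask], rcond=None)
    bg = (a @ coef).reshape(ny, nx)
    return PhaseImage(
        values=phase.values - bg,
        pixel_pitch_um=phase.pixel_pitch_um,
        time_min=phase.time_min,
    )
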