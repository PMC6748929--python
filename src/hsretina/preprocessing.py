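"""Raw-to-reflectance calibration, frame registration and spectral conditioning.

Calibration follows the standard dark/white normalisation
``R(lam) = (counts(lam) - dark - stray(lam)) / (white(lam) - dark)``
with the white reference taken from a Spectralon-lined model eye. Spectra
are then log-transformed (natural log) to make the multiplicative
interaction of illumination, media transmission and tissue reflectance
additive, and smoothed with a Savitzky–Golay filter (order 5, window 13).
"""

from __future__ import annotations

import logging
from typing import Union, overload

import numpy as np
from scipy.signal import savgol_filter

from .cube import HSCube, RawAcquisition, Spectrum
from .errors import CalibrationError, HsRetinaError, SamplingError
from .grids import WavelengthGrid

__all__ = [
    "calibrate_reflectance",
    "register_frames",
    "log_transform",
    "savgol_smooth",
    "DEFAULT_LOG_FLOOR",
    "SAVGOL_ORDER",
    "SAVGOL_WINDOW",
]

logger = logging.getLogger(__name__)

#: Reflectance floor applied before the log transform (guards shot-noise zeros).
DEFAULT_LOG_FLOOR = 1e-6

#: Savitzky–Golay defaults: 5th-order polynomial over a 13-sample window.
SAVGOL_ORDER = 5
SAVGOL_WINDOW = 13


def calibrate_reflectance(raw: RawAcquisition, **cube_metadata) -> HSCube:
    """Convert raw counts to reflectance via dark/white normalisation.

    Reflectance is clipped at zero from below (detector noise can push
    corrected counts slightly negative); no upper clip is applied, since
    specular structures can legitimately exceed the diffuse white standard.
    """
    white = raw.white[None, None, :]
    dark = raw.dark if np.isscalar(raw.dark) else np.asarray(raw.dark)[:, :, None]
    denom = white - dark
    if np.any(denom <= 0):
        bad = raw.grid.values[np.any(denom <= 0, axis=(0, 1))]
        raise CalibrationError(f"white <= dark at wavelengths {bad[:5]} nm")
    numer = raw.frames - dark - raw.internal_reflection[None, None, :]
    reflectance = numer / denom
    return HSCube(
        data=np.clip(reflectance, 0.0, None),
        grid=raw.grid,
        **cube_metadata,
    )


def _ncc_shift(frame: np.ndarray, reference: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (row, col) shift of `frame` maximising normalised cross-correlation
    with `reference`, searched over |shift| <= max_shift via FFT correlation of
    mean-subtracted images."""
    a = reference - reference.mean()
    b = frame - frame.mean()
    if a.std() == 0 or b.std() == 0:
        logger.warning("degenerate (constant) frame during registration; zero shift assumed")
        return (0, 0)
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    corr = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    rows = np.r_[0 : max_shift + 1, a.shape[0] - max_shift : a.shape[0]]
    cols = np.r_[0 : max_shift + 1, a.shape[1] - max_shift : a.shape[1]]
    window = corr[np.ix_(rows, cols)]
    i, j = np.unravel_index(np.argmax(window), window.shape)
    dr, dc = int(rows[i]), int(cols[j])
    if dr > a.shape[0] // 2:
        dr -= a.shape[0]
    if dc > a.shape[1] // 2:
        dc -= a.shape[1]
    return dr, dc


def register_frames(
    cube: HSCube, reference_index: int = 0, max_shift: int = 20
) -> tuple[HSCube, np.ndarray]:
    """Align frames by integer translation to the reference frame.

    Each frame's shift relative to its neighbour is estimated by maximising
    the normalised cross-correlation over integer translations up to
    ``max_shift`` pixels, and shifts are accumulated along the chain to the
    reference frame. Returns the registered cube together with a boolean
    validity mask (rows x cols): pixels shifted in from outside any frame
    are False there and must be excluded downstream. Registration is
    translation-only — sufficient for the residual inter-frame motion this
    stage models.
    """
    n = cube.shape[2]
    if n < 2:
        raise HsRetinaError("registration needs at least 2 frames")
    # shift of frame t relative to frame t-1
    pair_shifts = np.zeros((n, 2), dtype=int)
    for t in range(1, n):
        pair_shifts[t] = _ncc_shift(cube.data[:, :, t], cube.data[:, :, t - 1], max_shift)
    cumulative = np.cumsum(pair_shifts, axis=0)
    cumulative -= cumulative[reference_index]

    registered = np.empty_like(cube.data)
    valid = np.ones(cube.shape[:2], dtype=bool)
    for t in range(n):
        # cumulative[t] is the estimated shift convention (reference - frame),
        # which is exactly the roll that restores alignment
        dr, dc = cumulative[t]
        frame = np.roll(cube.data[:, :, t], (dr, dc), axis=(0, 1))
        frame_valid = np.ones(cube.shape[:2], dtype=bool)
        if dr > 0:
            frame[:dr], frame_valid[:dr] = 0, False
        elif dr < 0:
            frame[dr:], frame_valid[dr:] = 0, False
        if dc > 0:
            frame[:, :dc], frame_valid[:, :dc] = 0, False
        elif dc < 0:
            frame[:, dc:], frame_valid[:, dc:] = 0, False
        registered[:, :, t] = frame
        valid &= frame_valid
    out = HSCube(
        data=registered,
        grid=cube.grid,
        pixel_scale_um=cube.pixel_scale_um,
        subject_id=cube.subject_id,
        eye=cube.eye,
        session=cube.session,
        space=cube.space,
    )
    return out, valid


@overload
def log_transform(obj: Spectrum, floor: float = ...) -> Spectrum: ...
@overload
def log_transform(obj: HSCube, floor: float = ...) -> HSCube: ...


def log_transform(
    obj: Union[Spectrum, HSCube], floor: float = DEFAULT_LOG_FLOOR
) -> Union[Spectrum, HSCube]:
    """Natural log of reflectance, flooring values at ``floor`` first.

    The floor guards isolated shot-noise zeros; an all-zero input is a
    calibration failure, not noise, and raises.
    """
    if obj.space == "log":
        raise HsRetinaError("input is already in log space")
    values = obj.values if isinstance(obj, Spectrum) else obj.data
    if np.all(values <= 0):
        raise SamplingError("all-zero reflectance cannot be log-transformed")
    logged = np.log(np.maximum(values, floor))
    if isinstance(obj, Spectrum):
        return obj.with_values(logged, space="log")
    return HSCube(
        data=logged,
        grid=obj.grid,
        pixel_scale_um=obj.pixel_scale_um,
        subject_id=obj.subject_id,
        eye=obj.eye,
        session=obj.session,
        space="log",
    )


def savgol_smooth(
    spectrum: Spectrum, order: int = SAVGOL_ORDER, window: int = SAVGOL_WINDOW
) -> Spectrum:
    """Savitzky–Golay smoothing along the wavelength axis.

    Each value is replaced by the centre of a local least-squares polynomial
    fit of the given order over the window; the terminal half-windows are
    filled by evaluating the polynomial fitted to the first/last full window
    (scipy's ``mode='interp'``).
    """
    if window % 2 == 0:
        raise HsRetinaError(f"window must be odd, got {window}")
    if order >= window:
        raise HsRetinaError(f"order {order} must be < window {window}")
    if len(spectrum.values) < window:
        raise HsRetinaError(
            f"spectrum length {len(spectrum.values)} shorter than window {window}"
        )
    smoothed = savgol_filter(spectrum.values, window_length=window, polyorder=order, mode="interp")
    return spectrum.with_values(smoothed)
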