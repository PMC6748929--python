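"""Systematic retinal sampling.

The sampling template places six regions of interest on the fundus image,
oriented by the temporal raphe (the fovea -> optic-nerve-head axis): a
foveolar disc F1 (60 px diameter), a parafoveal annulus F2 (100-200 px
diameters), and four 200 x 200 px squares displaced perpendicular to the
raphe — S1/I1 superior/inferior to the fovea, S2/I2 superior/inferior to
the optic nerve head. Pixels overlying blood vessels are excluded from
every region using a difference-of-Gaussians (DoG) quantile rule: the 40%
of pixels with the highest DoG response are treated as vessel.

Image convention: row-major, origin top-left, (row, col) 0-based indices;
"superior" means decreasing row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .cube import HSCube, Spectrum
from .errors import GeometryError, HsRetinaError, SamplingError
from .grids import WavelengthGrid
from .preprocessing import SAVGOL_ORDER, SAVGOL_WINDOW, savgol_smooth

__all__ = [
    "Landmarks",
    "TemplateConfig",
    "ROISet",
    "VesselMask",
    "build_false_colour",
    "compute_raphe_angle",
    "build_roi_masks",
    "segment_vessels_human",
    "segment_vessels_mouse",
    "extract_roi_spectrum",
    "DEFAULT_BANDS_NM",
]

#: False-colour channel bands (nm): blue, green, red.
DEFAULT_BANDS_NM = {"blue": (450.0, 500.0), "green": (500.0, 580.0), "red": (600.0, 700.0)}

#: Fraction of pixels flagged as vessel by the DoG quantile rule.
DEFAULT_VESSEL_FRACTION = 0.40


@dataclass(frozen=True)
class Landmarks:
    """Manually selected fovea and optic-nerve-head centres, (row, col) px."""

    fovea_rc: tuple[float, float]
    onh_rc: tuple[float, float]

    def validate(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        for name, (r, c) in (("fovea", self.fovea_rc), ("onh", self.onh_rc)):
            if not (0 <= r < h and 0 <= c < w):
                raise GeometryError(f"{name} landmark {(r, c)} outside image {image_shape}")
        if self.fovea_rc == self.onh_rc:
            raise GeometryError("fovea and ONH landmarks coincide")


@dataclass(frozen=True)
class TemplateConfig:
    """Geometry of the six-ROI sampling template, in pixels.

    The perpendicular offsets of the squares from the fovea/ONH are not a
    published quantity; 300 px places 200 px squares clear of the arcades on
    a 30-degree fundus image and is configurable.
    """

    f1_diameter: float = 60.0
    f2_inner_diameter: float = 100.0
    f2_outer_diameter: float = 200.0
    square_side: float = 200.0
    delta_fovea: float = 300.0
    delta_onh: float = 300.0


@dataclass
class ROISet:
    """The six boolean ROI masks plus the raphe orientation used to place them."""

    masks: dict[str, np.ndarray]
    raphe_angle: float

    def __getitem__(self, key: str) -> np.ndarray:
        return self.masks[key]


@dataclass
class VesselMask:
    """Boolean vessel-exclusion mask; True = vessel, excluded from sampling."""

    mask: np.ndarray
    fraction: float


def build_false_colour(
    cube: HSCube, band_ranges: Optional[dict[str, tuple[float, float]]] = None
) -> np.ndarray:
    """False-colour composite: per-channel band means, percentile-stretched.

    Returns an (rows, cols, 3) float array in RGB order with each channel
    independently stretched to [0, 1] between its 1st and 99th percentiles.
    The green band (500-580 nm) straddles the haemoglobin bands, which is
    what makes the vasculature dark and prominent in the composite.
    """
    bands = band_ranges or DEFAULT_BANDS_NM
    channels = []
    for name in ("red", "green", "blue"):
        lo, hi = bands[name]
        idx = cube.grid.band_indices(lo, hi)
        ch = cube.data[:, :, idx].mean(axis=2)
        p1, p99 = np.percentile(ch, [1, 99])
        if p99 > p1:
            ch = np.clip((ch - p1) / (p99 - p1), 0.0, 1.0)
        else:
            ch = np.zeros_like(ch)
        channels.append(ch)
    return np.stack(channels, axis=-1)


def green_channel(cube: HSCube) -> np.ndarray:
    """Unstretched mean reflectance over the green band (500-580 nm)."""
    idx = cube.grid.band_indices(*DEFAULT_BANDS_NM["green"])
    return cube.data[:, :, idx].mean(axis=2)


def compute_raphe_angle(landmarks: Landmarks) -> float:
    """Orientation of the fovea -> ONH vector, radians in (-pi, pi].

    Zero means the ONH lies along increasing column (horizontal); positive
    angles rotate toward increasing row (downward on screen).
    """
    dr = landmarks.onh_rc[0] - landmarks.fovea_rc[0]
    dc = landmarks.onh_rc[1] - landmarks.fovea_rc[1]
    if dr == 0 and dc == 0:
        raise GeometryError("fovea and ONH landmarks coincide")
    angle = float(np.arctan2(dr, dc))
    if angle <= -np.pi:
        angle += 2 * np.pi
    return angle


def _disc_mask(shape, centre_rc, radius) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    d = np.hypot(rows - centre_rc[0], cols - centre_rc[1])
    return d <= radius


def _square_mask(shape, centre_rc, side, angle) -> np.ndarray:
    rows = np.arange(shape[0])[:, None] - centre_rc[0]
    cols = np.arange(shape[1])[None, :] - centre_rc[1]
    # coordinates along (u) and perpendicular to (v) the raphe axis
    u = rows * np.sin(angle) + cols * np.cos(angle)
    v = -rows * np.cos(angle) + cols * np.sin(angle)
    half = side / 2.0
    return (u >= -half) & (u < half) & (v >= -half) & (v < half)


def build_roi_masks(
    landmarks: Landmarks,
    image_shape: tuple[int, int],
    template: TemplateConfig = TemplateConfig(),
) -> ROISet:
    """Place the six-ROI template on an image, oriented by the raphe.

    S-regions sit on the superior (smaller-row for a horizontal raphe) side;
    rotating the landmarks rotates the whole template rigidly.
    """
    landmarks.validate(image_shape)
    angle = compute_raphe_angle(landmarks)
    # unit vector along the raphe and its superior-pointing perpendicular
    perp = np.array([-np.cos(angle), np.sin(angle)])  # (row, col); up when angle=0
    fovea = np.asarray(landmarks.fovea_rc, dtype=float)
    onh = np.asarray(landmarks.onh_rc, dtype=float)

    centres = {
        "F1": fovea,
        "F2": fovea,
        "S1": fovea + template.delta_fovea * perp,
        "I1": fovea - template.delta_fovea * perp,
        "S2": onh + template.delta_onh * perp,
        "I2": onh - template.delta_onh * perp,
    }
    extents = {
        "F1": template.f1_diameter / 2.0,
        "F2": template.f2_outer_diameter / 2.0,
        "S1": template.square_side / np.sqrt(2.0),
        "I1": template.square_side / np.sqrt(2.0),
        "S2": template.square_side / np.sqrt(2.0),
        "I2": template.square_side / np.sqrt(2.0),
    }
    h, w = image_shape
    offenders = [
        name
        for name, (r, c) in centres.items()
        if r - extents[name] < -0.5
        or c - extents[name] < -0.5
        or r + extents[name] > h - 0.5
        or c + extents[name] > w - 0.5
    ]
    if offenders:
        raise GeometryError(f"ROIs out of image bounds: {offenders}")

    masks = {
        "F1": _disc_mask(image_shape, fovea, template.f1_diameter / 2.0),
        "F2": _disc_mask(image_shape, fovea, template.f2_outer_diameter / 2.0)
        & ~_disc_mask(image_shape, fovea, template.f2_inner_diameter / 2.0),
    }
    for name in ("S1", "I1", "S2", "I2"):
        masks[name] = _square_mask(image_shape, centres[name], template.square_side, angle)
    return ROISet(masks=masks, raphe_angle=angle)


def _flag_top_fraction(response: np.ndarray, fraction: float) -> np.ndarray:
    """Flag the ceil(fraction * N) highest-response pixels.

    Ties are broken toward the lowest (row, col) lexicographic position, so
    the flagged count is exact and deterministic for any input, including a
    constant image.
    """
    n = response.size
    k = int(np.ceil(fraction * n))
    order = np.argsort(-response.ravel(), kind="stable")
    flat = np.zeros(n, dtype=bool)
    flat[order[:k]] = True
    return flat.reshape(response.shape)


def segment_vessels_human(
    green: np.ndarray,
    sigma_small: float = 1.0,
    sigma_large: float = 20.0,
    vessel_fraction: float = DEFAULT_VESSEL_FRACTION,
) -> VesselMask:
    """DoG vessel segmentation on the green channel.

    Response = Gaussian(sigma_large) * I - Gaussian(sigma_small) * I, so
    locally dark curvilinear structures (vessels in the green band) score
    high; the top ``vessel_fraction`` of pixels are flagged. The flagged
    count is exactly ``ceil(fraction * N)`` for every input.
    """
    green = np.asarray(green, dtype=float)
    if green.ndim != 2:
        raise TypeError(f"expected a 2-D image, got ndim={green.ndim}")
    if not np.all(np.isfinite(green)):
        raise HsRetinaError("image contains non-finite values")
    dog = gaussian_filter(green, sigma_large) - gaussian_filter(green, sigma_small)
    mask = _flag_top_fraction(dog, vessel_fraction)
    return VesselMask(mask=mask, fraction=mask.mean())


def segment_vessels_mouse(
    mean_image: np.ndarray,
    small_sigmas: Sequence[float] = tuple(np.round(np.arange(1.0, 5.0 + 1e-9, 0.2), 1)),
    large_sigmas: Sequence[float] = tuple(np.arange(4.0, 14.0 + 1e-9, 1.0)),
    vessel_fraction: float = DEFAULT_VESSEL_FRACTION,
    onh_rc: Optional[tuple[float, float]] = None,
    onh_radius_px: float = 0.0,
) -> VesselMask:
    """Multi-scale DoG vessel segmentation for the mouse fundus.

    The response is the maximum signed DoG over every (sigma_small,
    sigma_large) pair with sigma_small < sigma_large, capturing vessels
    across a range of calibres; thresholding is identical to the human
    variant. The input is the mean image over 390-460 nm (see
    :func:`mouse_segmentation_image`). If an optic-nerve-head centre is
    given, a disc of ``onh_radius_px`` around it is also flagged (the ONH is
    excluded along with the vessels).
    """
    img = np.asarray(mean_image, dtype=float)
    if img.ndim != 2:
        raise TypeError(f"expected a 2-D image, got ndim={img.ndim}")
    blurs: dict[float, np.ndarray] = {}

    def blur(sigma: float) -> np.ndarray:
        if sigma not in blurs:
            blurs[sigma] = gaussian_filter(img, sigma)
        return blurs[sigma]

    response = None
    for ss in small_sigmas:
        for sl in large_sigmas:
            if ss >= sl:
                continue
            dog = blur(sl) - blur(ss)
            response = dog if response is None else np.maximum(response, dog)
    if response is None:
        raise HsRetinaError("no valid (sigma_small < sigma_large) pair")
    mask = _flag_top_fraction(response, vessel_fraction)
    if onh_rc is not None and onh_radius_px > 0:
        mask = mask | _disc_mask(img.shape, onh_rc, onh_radius_px)
    return VesselMask(mask=mask, fraction=mask.mean())


def mouse_segmentation_image(cube: HSCube, low_nm: float = 390.0, high_nm: float = 460.0) -> np.ndarray:
    """Mean image over the 390-460 nm band used for mouse vessel segmentation."""
    idx = cube.grid.band_indices(low_nm, high_nm)
    return cube.data[:, :, idx].mean(axis=2)


def extract_roi_spectrum(
    cube: HSCube,
    roi_mask: np.ndarray,
    vessel_mask: Optional[VesselMask | np.ndarray] = None,
    valid_mask: Optional[np.ndarray] = None,
    location_id: str = "",
    smooth: bool = True,
) -> Spectrum:
    """Mean log-spectrum over an ROI, vessels and invalid pixels excluded.

    The cube must already be log-transformed (averaging happens in log
    space). The ROI-mean spectrum is Savitzky-Golay smoothed (order 5,
    window 13) unless ``smooth=False``.
    """
    if cube.space != "log":
        raise SamplingError("extract_roi_spectrum requires a log-space cube")
    keep = np.asarray(roi_mask, dtype=bool).copy()
    if vessel_mask is not None:
        vm = vessel_mask.mask if isinstance(vessel_mask, VesselMask) else vessel_mask
        keep &= ~np.asarray(vm, dtype=bool)
    if valid_mask is not None:
        keep &= np.asarray(valid_mask, dtype=bool)
    if not keep.any():
        raise SamplingError(f"ROI {location_id or '?'} has no usable pixels")
    mean = cube.data[keep].mean(axis=0)
    spectrum = Spectrum(
        values=mean,
        grid=cube.grid,
        space="log",
        subject_id=cube.subject_id,
        location_id=location_id,
        eye=cube.eye,
        session=cube.session,
    )
    if smooth:
        spectrum = savgol_smooth(spectrum, SAVGOL_ORDER, SAVGOL_WINDOW)
    return spectrum
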