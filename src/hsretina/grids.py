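"""Wavelength grids.

All spectral arrays in the package are indexed by a :class:`WavelengthGrid`
whose values are stored in *ascending* nanometre order, regardless of the
acquisition scan direction (the human camera scans 900 -> 450 nm; that order
is metadata, never the storage convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError

__all__ = [
    "WavelengthGrid",
    "make_grid",
    "human_grid",
    "mouse_grid",
    "mouse_model_grid",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform, strictly increasing wavelength axis in nanometres."""

    start_nm: float
    end_nm: float
    step_nm: float
    values: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.end_nm <= self.start_nm:
            raise GridError(f"end_nm {self.end_nm} must exceed start_nm {self.start_nm}")
        if self.step_nm <= 0:
            raise GridError(f"step_nm must be positive, got {self.step_nm}")
        span = self.end_nm - self.start_nm
        n_steps = span / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise GridError(
                f"step {self.step_nm} nm does not divide the range "
                f"[{self.start_nm}, {self.end_nm}] nm exactly"
            )
        values = self.start_nm + self.step_nm * np.arange(int(round(n_steps)) + 1)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.start_nm == other.start_nm
            and self.end_nm == other.end_nm
            and self.step_nm == other.step_nm
        )

    def __hash__(self) -> int:
        return hash((self.start_nm, self.end_nm, self.step_nm))

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an exact grid wavelength; raises GridError if absent."""
        idx = (wavelength_nm - self.start_nm) / self.step_nm
        if idx < 0 or idx > len(self) - 1 or abs(idx - round(idx)) > 1e-9:
            raise GridError(f"{wavelength_nm} nm is not on the grid")
        return int(round(idx))

    def band_indices(self, low_nm: float, high_nm: float) -> np.ndarray:
        """Indices of grid wavelengths in [low_nm, high_nm] (inclusive)."""
        mask = (self.values >= low_nm - 1e-9) & (self.values <= high_nm + 1e-9)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise GridError(f"band [{low_nm}, {high_nm}] nm contains no grid wavelength")
        return idx

    def contains_range(self, other: "WavelengthGrid") -> bool:
        return other.start_nm >= self.start_nm - 1e-9 and other.end_nm <= self.end_nm + 1e-9


def make_grid(start_nm: float, end_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a uniform wavelength grid covering [start_nm, end_nm]."""
    return WavelengthGrid(start_nm=start_nm, end_nm=end_nm, step_nm=step_nm)


def human_grid() -> WavelengthGrid:
    """The human camera grid: 450-900 nm in 5 nm steps, 91 wavelengths."""
    return make_grid(450.0, 900.0, 5.0)


def mouse_grid() -> WavelengthGrid:
    """The mouse bench-ophthalmoscope grid: 320-680 nm in 1 nm steps."""
    return make_grid(320.0, 680.0, 1.0)


def mouse_model_grid() -> WavelengthGrid:
    """Grid shared by mouse spectra and the recalibrated model: 450-680/5 nm."""
    return make_grid(450.0, 680.0, 5.0)
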