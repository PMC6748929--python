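"""Core containers and cube I/O.

A hyperspectral cube is a (rows, cols, wavelengths) array of reflectance
with an attached :class:`~hsretina.grids.WavelengthGrid`. Cubes are stored
on disk as multi-page TIFF stacks, one page per wavelength in ascending
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, GridError, CohortError
from .grids import WavelengthGrid

__all__ = [
    "HSCube",
    "RawAcquisition",
    "Spectrum",
    "SpectrumMatrix",
    "HSScoreTable",
    "read_cube",
    "write_cube",
    "LOCATIONS",
]

#: The six retinal sampling locations plus the whole-retina aggregate.
LOCATIONS = ("F1", "F2", "S1", "S2", "I1", "I2")

#: Nominal pixel pitch of the human camera, microns. Metadata only.
DEFAULT_PIXEL_SCALE_UM = 8.3


@dataclass
class HSCube:
    """Reflectance cube: rows x cols x wavelengths, values >= 0 and finite."""

    data: np.ndarray
    grid: WavelengthGrid
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    subject_id: str = ""
    eye: str = ""
    session: str = ""
    space: Literal["reflectance", "log"] = "reflectance"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"cube data must be 3-D, got ndim={self.data.ndim}")
        if self.data.shape[2] != len(self.grid):
            raise GridError(
                f"cube has {self.data.shape[2]} planes but grid has {len(self.grid)} wavelengths"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("cube contains non-finite values")
        if self.space == "reflectance" and np.any(self.data < 0):
            raise FormatError("reflectance cube contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel_spectrum(self, row: int, col: int) -> "Spectrum":
        return Spectrum(
            values=self.data[row, col].copy(),
            grid=self.grid,
            space=self.space,
            subject_id=self.subject_id,
            eye=self.eye,
            session=self.session,
        )


@dataclass
class RawAcquisition:
    """Raw camera counts with dark/white calibration references.

    ``white`` is the per-wavelength Spectralon model-eye reading and must
    exceed ``dark`` everywhere; ``internal_reflection`` is an optional
    per-wavelength stray-light offset (defaults to zero — the camera
    vendor's estimation procedure is proprietary).
    """

    frames: np.ndarray
    dark: np.ndarray | float
    white: np.ndarray
    grid: WavelengthGrid
    internal_reflection: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("raw frames must be 3-D (rows, cols, wavelengths)")
        if self.frames.shape[2] != len(self.grid):
            raise GridError("raw frame count does not match grid")
        self.white = np.broadcast_to(np.asarray(self.white, dtype=float), (len(self.grid),)).copy()
        if np.isscalar(self.dark):
            self.dark = float(self.dark)
        else:
            self.dark = np.asarray(self.dark, dtype=float)
        if self.internal_reflection is None:
            self.internal_reflection = np.zeros(len(self.grid))
        else:
            self.internal_reflection = np.broadcast_to(
                np.asarray(self.internal_reflection, dtype=float), (len(self.grid),)
            ).copy()


@dataclass
class Spectrum:
    """A single per-wavelength trace, in reflectance or log space."""

    values: np.ndarray
    grid: WavelengthGrid
    space: Literal["reflectance", "log"] = "reflectance"
    subject_id: str = ""
    location_id: str = ""
    eye: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("spectrum values must be 1-D")
        if self.values.shape[0] != len(self.grid):
            raise GridError(
                f"spectrum has {self.values.shape[0]} values but grid has {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("spectrum contains non-finite values")

    def with_values(self, values: np.ndarray, **changes) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


@dataclass
class SpectrumMatrix:
    """Cohort matrix of log-spectra: one row per subject acquisition.

    Rows share a single grid and sampling location; ``labels`` holds the
    per-row group ('case' or 'control').
    """

    X: np.ndarray
    labels: np.ndarray
    grid: WavelengthGrid
    location_id: str = ""
    subject_ids: Optional[Sequence[str]] = None
    eyes: Optional[Sequence[str]] = None
    sessions: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise FormatError("spectrum matrix must be 2-D")
        if self.X.shape[1] != len(self.grid):
            raise GridError("spectrum matrix width does not match grid")
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.X.shape[0]:
            raise CohortError("one label required per row")
        bad = set(np.unique(self.labels)) - {"case", "control"}
        if bad:
            raise CohortError(f"unknown group labels: {sorted(bad)}")
        if self.subject_ids is None:
            self.subject_ids = [f"S{i:03d}" for i in range(self.X.shape[0])]
        self.subject_ids = list(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def class_rows(self, label: str) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


@dataclass
class HSScoreTable:
    """Per-(subject, eye, location) HS scores as a tidy DataFrame."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["subject_id", "eye", "location_id", "score", "label"]
    ))

    REQUIRED = ("subject_id", "eye", "location_id", "score", "label")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise CohortError(f"score table missing columns {missing}")
        dup = self.frame.duplicated(["subject_id", "eye", "location_id"])
        if dup.any():
            raise CohortError("duplicate (subject, eye, location) rows in score table")

    def scores_for(self, location_id: str) -> pd.DataFrame:
        return self.frame[self.frame["location_id"] == location_id]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "HSScoreTable":
        return cls(frame=pd.read_csv(path))


def read_cube(path: str | Path, grid: WavelengthGrid, **metadata) -> HSCube:
    """Read a multi-page TIFF stack into an :class:`HSCube`.

    Pages are assumed stored in ascending-wavelength order (the package's
    canonical order; :func:`write_cube` guarantees it). Pass
    ``descending=True`` in metadata for stacks saved in camera scan order.
    """
    path = Path(path)
    descending = bool(metadata.pop("descending", False))
    try:
        stack = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{path} is not a readable TIFF stack: {exc}") from exc
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D page stack, got ndim={stack.ndim}")
    if stack.shape[0] != len(grid):
        raise GridError(
            f"{path} has {stack.shape[0]} pages but grid expects {len(grid)}"
        )
    if descending:
        stack = stack[::-1]
    data = np.moveaxis(stack, 0, -1).astype(float)
    return HSCube(data=data, grid=grid, **metadata)


def write_cube(cube: HSCube, path: str | Path) -> Path:
    """Write a cube as a multi-page TIFF, ascending-wavelength page order."""
    path = Path(path)
    pages = np.moveaxis(cube.data, -1, 0)
    tifffile.imwrite(path, np.ascontiguousarray(pages), photometric="minisblack")
    return path
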