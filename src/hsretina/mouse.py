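"""Mouse-specific pipeline stages.

The mouse retina is too small for the six-region human template, so each
retina contributes a single whole-retina mean spectrum (vessels and optic
nerve head excluded). Retinas whose intensity falls more than three median
absolute deviations below the cohort median at over half the wavelengths
are excluded as acquisition failures. Because the animals were imaged in
two sessions with slightly different illumination, a per-session offset —
the session's control-mean spectrum minus the pooled control mean — is
subtracted from every spectrum in that session before scoring with the
recalibrated (450-680 nm) human model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cube import HSCube, HSScoreTable, Spectrum, SpectrumMatrix
from .dropd import DropDModel, recalibrate_model, resample_spectrum, score
from .errors import CohortError, SamplingError
from .grids import WavelengthGrid, mouse_model_grid
from .preprocessing import log_transform
from .sampling import VesselMask, mouse_segmentation_image, segment_vessels_mouse
from .stats import RocResult, roc_auc

__all__ = [
    "retina_mean_spectrum",
    "exclude_outlier_retinas",
    "compensate_sessions",
    "MousePipelineConfig",
    "run_mouse_pipeline",
]


def retina_mean_spectrum(cube: HSCube, exclusion: Optional[VesselMask | np.ndarray] = None) -> Spectrum:
    """Whole-retina mean spectrum over non-excluded pixels."""
    if exclusion is None:
        keep = np.ones(cube.shape[:2], dtype=bool)
    else:
        mask = exclusion.mask if isinstance(exclusion, VesselMask) else np.asarray(exclusion, bool)
        keep = ~mask
    if not keep.any():
        raise SamplingError("no retained pixels for whole-retina spectrum")
    return Spectrum(
        values=cube.data[keep].mean(axis=0),
        grid=cube.grid,
        space=cube.space,
        subject_id=cube.subject_id,
        location_id="WHOLE",
        eye=cube.eye,
        session=cube.session,
    )


def exclude_outlier_retinas(spectra: Sequence[Spectrum]) -> tuple[list[Spectrum], list[str]]:
    """Drop retinas that are dim outliers under the cohort MAD rule.

    At each wavelength the cohort median and (unscaled) median absolute
    deviation are computed; an animal is flagged at that wavelength if its
    value lies strictly below ``median - 3*MAD``, and excluded if flagged
    at strictly more than 50% of wavelengths. Both inequalities are strict,
    so identical spectra (MAD = 0) are never excluded.
    """
    if len(spectra) < 3:
        raise CohortError("outlier exclusion needs >= 3 retinas")
    grid = spectra[0].grid
    if any(s.grid != grid for s in spectra):
        raise CohortError("all spectra must share one grid")
    V = np.vstack([s.values for s in spectra])
    median = np.median(V, axis=0)
    mad = np.median(np.abs(V - median), axis=0)
    flagged = V < (median - 3.0 * mad)
    frac = flagged.mean(axis=1)
    excluded = [s.subject_id for s, f in zip(spectra, frac) if f > 0.5]
    kept = [s for s, f in zip(spectra, frac) if f <= 0.5]
    return kept, excluded


def compensate_sessions(
    spectra: Sequence[Spectrum], control_ids: Sequence[str]
) -> list[Spectrum]:
    """Remove per-session illumination offsets using control animals.

    For each session, the offset is that session's mean control spectrum
    minus the pooled control mean; it is subtracted (log space) from every
    spectrum in the session. Within-session differences between any two
    animals are untouched.
    """
    control_ids = set(control_ids)
    sessions = sorted({s.session for s in spectra})
    controls = [s for s in spectra if s.subject_id in control_ids]
    if not controls:
        raise CohortError("no control animals in cohort")
    pooled = np.mean([s.values for s in controls], axis=0)
    offsets: dict[str, np.ndarray] = {}
    for sess in sessions:
        sess_controls = [s.values for s in controls if s.session == sess]
        if not sess_controls:
            raise CohortError(f"session {sess!r} has no control animal")
        offsets[sess] = np.mean(sess_controls, axis=0) - pooled
    return [s.with_values(s.values - offsets[s.session]) for s in spectra]


@dataclass(frozen=True)
class MousePipelineConfig:
    """Settings for the end-to-end mouse run."""

    model_grid: WavelengthGrid = field(default_factory=mouse_model_grid)
    k: Optional[int] = None  # None = re-select by LOO on the restricted grid
    k_max: int = 4
    vessel_fraction: float = 0.40
    onh_radius_px: float = 0.0
    log_floor: float = 1e-6


def run_mouse_pipeline(
    cubes: Sequence[HSCube],
    labels: Mapping[str, str],
    human_training_data: SpectrumMatrix,
    config: MousePipelineConfig = MousePipelineConfig(),
    onh_landmarks: Optional[Mapping[str, tuple[float, float]]] = None,
) -> tuple[HSScoreTable, RocResult, DropDModel, list[str]]:
    """Score a mouse cohort with the recalibrated human model.

    Stages: multi-scale DoG vessel (+ONH) exclusion -> whole-retina mean
    spectrum -> log transform -> linear resampling to 450-680/5 nm -> MAD
    outlier exclusion -> session compensation -> HS scoring with the human
    model recalibrated to the mouse range -> ROC. Returns the score table,
    the ROC result, the recalibrated model and the excluded animal ids.
    """
    spectra: list[Spectrum] = []
    for cube in cubes:
        try:
            seg_img = mouse_segmentation_image(cube)
            onh = (onh_landmarks or {}).get(cube.subject_id)
            vessels = segment_vessels_mouse(
                seg_img,
                vessel_fraction=config.vessel_fraction,
                onh_rc=onh,
                onh_radius_px=config.onh_radius_px if onh is not None else 0.0,
            )
            mean_spec = retina_mean_spectrum(cube, vessels)
            log_spec = log_transform(mean_spec, floor=config.log_floor)
            spectra.append(resample_spectrum(log_spec, config.model_grid))
        except Exception as exc:
            raise type(exc)(f"[subject {cube.subject_id}] {exc}") from exc

    kept, excluded = exclude_outlier_retinas(spectra)
    control_ids = [sid for sid, lab in labels.items() if lab == "control"]
    compensated = compensate_sessions(kept, control_ids)

    model = recalibrate_model(human_training_data, config.model_grid,
                              k=config.k, k_max=config.k_max)
    rows = [
        {
            "subject_id": s.subject_id,
            "eye": s.eye,
            "location_id": "WHOLE",
            "score": score(model, s),
            "label": labels[s.subject_id],
        }
        for s in compensated
    ]
    table = HSScoreTable(frame=pd.DataFrame(rows))
    roc = roc_auc(table.frame["score"].to_numpy(), table.frame["label"].to_numpy())
    return table, roc, model, excluded
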