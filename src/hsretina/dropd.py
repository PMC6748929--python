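"""DROP-D: Dimension Reduction by Orthogonal Projection for Discrimination.

The discriminant works in two steps. First it estimates the main spectral
axes of *within-class* variability — sources such as lens yellowing, fundus
pigmentation and haemoglobin content that differ between eyes but carry no
group information — and removes them by orthogonal projection. Second it
takes the principal axis of *between-class* variability of the deflated
data as the spectral model ``b``; for two classes this is the deflated
difference of the class mean spectra. A subject's hyperspectral (HS) score
is the inner product of their mean-centred log-spectrum with ``b``.

Because ``b`` is orthogonal to every removed axis, HS scores are invariant
to any linear combination of the removed within-class axes — the property
that makes the method robust in the small-n / many-wavelengths regime.

Model order (how many axes to remove) is chosen by leave-one-out
cross-validation, maximising the AUC of the held-out scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import json
import numpy as np
import pandas as pd

from .cube import HSScoreTable, LOCATIONS, Spectrum, SpectrumMatrix
from .errors import GridError, ModelError, CohortError
from .grids import WavelengthGrid, make_grid
from .synthetic import ConstituentBasis

__all__ = [
    "DropDModel",
    "CvCurve",
    "ConstituentFit",
    "fit_dropd",
    "score",
    "score_matrix",
    "select_k_loocv",
    "fit_constituents",
    "resample_spectrum",
    "recalibrate_model",
    "aggregate_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class DropDModel:
    """A trained DROP-D discriminant.

    ``W`` (wavelengths x k, orthonormal columns) holds the removed
    within-class axes; ``b`` (unit norm, orthogonal to W) is the spectral
    model; ``mu`` is the training grand-mean spectrum. The sign of ``b`` is
    fixed so the mean training case score exceeds the mean control score.
    """

    mu: np.ndarray
    W: np.ndarray
    b: np.ndarray
    k: int
    grid: WavelengthGrid
    location_id: str = ""

    def __post_init__(self) -> None:
        p = len(self.grid)
        self.mu = np.asarray(self.mu, dtype=float)
        self.W = np.asarray(self.W, dtype=float).reshape(p, -1) if self.k else np.zeros((p, 0))
        self.b = np.asarray(self.b, dtype=float)
        if self.mu.shape != (p,) or self.b.shape != (p,) or self.W.shape != (p, self.k):
            raise ModelError("model component shapes inconsistent with grid")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "grid": {"start_nm": self.grid.start_nm, "end_nm": self.grid.end_nm,
                     "step_nm": self.grid.step_nm},
            "mu": self.mu.tolist(),
            "W": self.W.tolist(),
            "b": self.b.tolist(),
            "k": self.k,
            "location_id": self.location_id,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DropDModel":
        payload = json.loads(Path(path).read_text())
        grid = make_grid(**payload["grid"])
        return cls(
            mu=np.array(payload["mu"]),
            W=np.array(payload["W"]).reshape(len(grid), -1),
            b=np.array(payload["b"]),
            k=payload["k"],
            grid=grid,
            location_id=payload["location_id"],
        )


@dataclass
class CvCurve:
    """Leave-one-out criterion (AUC) per candidate model order."""

    k_values: np.ndarray
    criterion: np.ndarray
    chosen_k: int
    flat: bool = False  # True when no k clearly beats chance


@dataclass
class ConstituentFit:
    """OLS decomposition of a unit-norm spectral axis onto constituent curves."""

    coefficients: dict[str, float]
    intercept: float
    rmse_percent: float
    fitted: np.ndarray
    residual: np.ndarray


def _class_means(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return X[labels == "case"].mean(axis=0), X[labels == "control"].mean(axis=0)


def _fix_column_signs(W: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (bit-reproducible)."""
    for j in range(W.shape[1]):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def fit_dropd(data: SpectrumMatrix, k: int, location_id: Optional[str] = None) -> DropDModel:
    """Fit the two-step orthogonal-projection discriminant.

    1. Centre each row by its class mean; the top-``k`` right singular
       vectors of this within-class-centred matrix are the removed axes W.
    2. Deflate the grand-mean-centred class means onto the orthogonal
       complement of span(W); ``b`` is the principal axis of the
       class-size-weighted between-class scatter of the deflated means —
       for two classes, the normalised deflated mean difference.
    """
    X, labels = data.X, data.labels
    n, p = X.shape
    n_case = int((labels == "case").sum())
    n_control = n - n_case
    if n_case < 1 or n_control < 1:
        raise CohortError("both classes must be present for training")
    if k < 0 or k > min(n - 2, p):
        raise ModelError(f"k={k} outside [0, {min(n - 2, p)}]")

    mu = X.mean(axis=0)
    mu_case, mu_control = _class_means(X, labels)
    within = X.copy()
    within[labels == "case"] -= mu_case
    within[labels == "control"] -= mu_control

    if k > 0:
        _, _, Vt = np.linalg.svd(within, full_matrices=False)
        W = _fix_column_signs(Vt[:k].T.copy())
    else:
        W = np.zeros((p, 0))

    def deflate(v: np.ndarray) -> np.ndarray:
        return v - W @ (W.T @ v) if k else v

    diff = deflate(mu_case - mu_control)
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ModelError("class means coincide after deflation; no discriminant axis")
    b = diff / norm
    # sign convention: mean case score >= mean control score (already true for
    # b along case-minus-control, but enforce explicitly)
    if (mu_case - mu) @ b < (mu_control - mu) @ b:
        b = -b
    return DropDModel(mu=mu, W=W, b=b, k=k, grid=data.grid,
                      location_id=location_id or data.location_id)


def score(model: DropDModel, spectrum: Spectrum | np.ndarray) -> float:
    """HS score of a spectrum: inner product of the centred values with b."""
    if isinstance(spectrum, Spectrum):
        if spectrum.grid != model.grid:
            raise GridError("spectrum grid does not match model grid")
        if spectrum.space != "log":
            raise ModelError("HS scores are defined on log-space spectra")
        values = spectrum.values
    else:
        values = np.asarray(spectrum, dtype=float)
        if values.shape != model.mu.shape:
            raise GridError("spectrum length does not match model grid")
    return float((values - model.mu) @ model.b)


def score_matrix(model: DropDModel, data: SpectrumMatrix) -> np.ndarray:
    """HS scores for every row of a cohort matrix."""
    if data.grid != model.grid:
        raise GridError("matrix grid does not match model grid")
    return (data.X - model.mu) @ model.b


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of case scores over control scores, ties counted 1/2."""
    case = scores[labels == "case"]
    control = scores[labels == "control"]
    greater = (case[:, None] > control[None, :]).sum()
    ties = (case[:, None] == control[None, :]).sum()
    return (greater + 0.5 * ties) / (len(case) * len(control))


def select_k_loocv(data: SpectrumMatrix, k_max: int) -> CvCurve:
    """Choose the number of removed axes by leave-one-out cross-validation.

    For each candidate k, every subject is held out in turn, the model is
    refit on the rest and the held-out spectrum scored; the criterion is
    the AUC of the n held-out scores against the true labels. The chosen k
    maximises the criterion, ties broken toward the smallest k.
    """
    X, labels = data.X, data.labels
    n = X.shape[0]
    if n < 4 or (labels == "case").sum() < 2 or (labels == "control").sum() < 2:
        raise CohortError("LOO selection needs n >= 4 with >= 2 per class")
    hard_max = n - 3  # every LOO training fold must satisfy k <= n_train - 2
    if k_max > hard_max:
        warnings.warn(f"k_max clipped from {k_max} to {hard_max}", stacklevel=2)
        k_max = hard_max
    k_values = np.arange(k_max + 1)
    held_out = np.zeros((len(k_values), n))
    for i in range(n):
        keep = np.arange(n) != i
        fold = SpectrumMatrix(X=X[keep], labels=labels[keep], grid=data.grid,
                              location_id=data.location_id)
        for ki, k in enumerate(k_values):
            model = fit_dropd(fold, int(k))
            held_out[ki, i] = score(model, X[i])
    criterion = np.array([_auc(held_out[ki], labels) for ki in range(len(k_values))])
    chosen = int(k_values[np.argmax(criterion)])  # argmax takes the first (smallest k) on ties
    flat = bool(np.all(np.abs(criterion - 0.5) < 0.1))
    if flat:
        logger.warning("LOO criterion is flat near 0.5; no model order is informative")
    return CvCurve(k_values=k_values, criterion=criterion, chosen_k=chosen, flat=flat)


def fit_constituents(
    axis: np.ndarray | Spectrum,
    basis: ConstituentBasis,
    include: Optional[Sequence[str]] = None,
) -> ConstituentFit:
    """OLS fit of a unit-norm spectral axis on constituent curves + intercept.

    ``rmse_percent`` is 100x the root-mean-square residual of the fit; on a
    unit-norm axis this is the sub-percent figure used to judge how fully
    an axis is explained by known ocular constituents.
    """
    values = axis.values if isinstance(axis, Spectrum) else np.asarray(axis, dtype=float)
    if values.shape[0] != len(basis.grid):
        raise GridError("axis length does not match basis grid")
    names = list(include) if include is not None else [n for n in basis.names]
    cols = [basis.column(n) for n in names]
    design = np.column_stack([np.ones_like(values)] + cols)
    solution, _, rank, _ = np.linalg.lstsq(design, values, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient constituent basis; minimum-norm solution returned",
                      stacklevel=2)
    fitted = design @ solution
    residual = values - fitted
    return ConstituentFit(
        coefficients=dict(zip(names, solution[1:])),
        intercept=float(solution[0]),
        rmse_percent=float(100.0 * np.sqrt(np.mean(residual**2))),
        fitted=fitted,
        residual=residual,
    )


def resample_spectrum(spectrum: Spectrum, new_grid: WavelengthGrid) -> Spectrum:
    """Linear interpolation of a spectrum onto a new grid (no extrapolation)."""
    old = spectrum.grid
    if new_grid.start_nm < old.start_nm - 1e-9 or new_grid.end_nm > old.end_nm + 1e-9:
        raise GridError(
            f"new grid [{new_grid.start_nm}, {new_grid.end_nm}] nm extends beyond "
            f"[{old.start_nm}, {old.end_nm}] nm"
        )
    values = np.interp(new_grid.values, old.values, spectrum.values)
    return Spectrum(
        values=values,
        grid=new_grid,
        space=spectrum.space,
        subject_id=spectrum.subject_id,
        location_id=spectrum.location_id,
        eye=spectrum.eye,
        session=spectrum.session,
    )


def _restrict_matrix(data: SpectrumMatrix, new_grid: WavelengthGrid) -> SpectrumMatrix:
    rows = [
        np.interp(new_grid.values, data.grid.values, data.X[i])
        for i in range(data.n_subjects)
    ]
    return SpectrumMatrix(
        X=np.vstack(rows),
        labels=data.labels,
        grid=new_grid,
        location_id=data.location_id,
        subject_ids=data.subject_ids,
    )


def recalibrate_model(
    data: SpectrumMatrix,
    new_grid: WavelengthGrid,
    k: Optional[int] = None,
    k_max: int = 4,
) -> DropDModel:
    """Re-train the discriminant on a restricted wavelength range.

    The training spectra are resampled onto ``new_grid`` (which must lie
    within the original range) and the model is refit — with the given k,
    or with k re-selected by leave-one-out cross-validation when k is None.
    Used to transfer the human model to the narrower mouse camera range
    (450-680 nm).
    """
    if not data.grid.contains_range(new_grid):
        raise GridError("new grid extends beyond the training grid range")
    restricted = _restrict_matrix(data, new_grid)
    if k is None:
        k = select_k_loocv(restricted, k_max=k_max).chosen_k
    return fit_dropd(restricted, k)


def aggregate_scores(table: HSScoreTable) -> HSScoreTable:
    """Append per-subject 'overall' rows: the mean over the six locations."""
    frame = table.frame[table.frame["location_id"] != "overall"].copy()
    overall_rows = []
    for (subject, eye), grp in frame.groupby(["subject_id", "eye"], sort=False):
        present = set(grp["location_id"])
        missing = [loc for loc in LOCATIONS if loc not in present]
        if missing:
            raise CohortError(f"subject {subject} ({eye}) missing locations {missing}")
        sub = grp[grp["location_id"].isin(LOCATIONS)]
        overall_rows.append({
            "subject_id": subject,
            "eye": eye,
            "location_id": "overall",
            "score": sub["score"].mean(),
            "label": grp["label"].iloc[0],
        })
    out = pd.concat([frame, pd.DataFrame(overall_rows)], ignore_index=True)
    return HSScoreTable(frame=out)
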