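"""End-to-end human study on synthetic cohorts.

``run_human_study`` reproduces the analysis flow of the human study on
generated data: per-location cohort spectra for the study eyes of a
principal cohort, DROP-D training with leave-one-out model-order selection
at each of the six sampling locations, scoring of the study eyes, the
fellow eyes and an independent validation cohort, aggregation to an
'overall' score, and the downstream statistics (location-wise t tests with
Benjamini-Yekutieli correction, the repeated-measures group effect, ROC per
cohort, and the correlation of overall scores with a synthetic amyloid-
burden covariate).

Cohort sizes default to the study's: principal 15 cases / 20 controls
(study eyes), fellow eyes 15/19, validation 4/13.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cube import HSScoreTable, LOCATIONS, SpectrumMatrix
from .dropd import (
    CvCurve,
    DropDModel,
    aggregate_scores,
    fit_dropd,
    score_matrix,
    select_k_loocv,
)
from .grids import human_grid
from .stats import by_fdr, pearson_corr, rm_anova_group_effect, roc_auc, ttest_from_samples
from .synthetic import SyntheticCohortConfig, simulate_multisite_cohort

__all__ = ["HumanStudyConfig", "HumanStudyReport", "run_human_study"]


@dataclass(frozen=True)
class HumanStudyConfig:
    """Settings for the synthetic end-to-end human study."""

    n_case: int = 15
    n_control: int = 20
    n_fellow_case: int = 15
    n_fellow_control: int = 19
    n_validation_case: int = 4
    n_validation_control: int = 13
    effect_size: float = 8.0
    noise_sd: float = 0.02
    k_max: int = 4
    fdr_q: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HumanStudyConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


@dataclass
class HumanStudyReport:
    """Everything the end-to-end run computes, ready to serialise."""

    config: HumanStudyConfig
    models: dict[str, DropDModel]
    cv_curves: dict[str, CvCurve]
    scores: dict[str, HSScoreTable]  # cohort name -> table with overall rows
    location_tests: pd.DataFrame
    fdr_reject: dict[str, bool]
    anova: object
    roc: dict[str, object]
    pet_correlation: object

    def summary(self) -> dict:
        return {
            "chosen_k": {loc: cv.chosen_k for loc, cv in self.cv_curves.items()},
            "auc": {name: r.auc for name, r in self.roc.items()},
            "anova_F": self.anova.F,
            "anova_df": [self.anova.df1, self.anova.df2],
            "anova_p": self.anova.p,
            "pet_r": self.pet_correlation.r,
            "fdr_reject": self.fdr_reject,
        }

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.scores.items():
            table.to_csv(out / f"scores_{name}.csv")
        self.location_tests.to_csv(out / "location_tests.csv", index=False)
        payload = {"config": dataclasses.asdict(self.config)}
        payload["config"].pop("grid", None)
        payload.update(self.summary())
        (out / "report.json").write_text(json.dumps(payload, indent=2, default=float))
        return out


def _cohort_seed(base_seed: int, cohort_index: int) -> int:
    return (base_seed * 1_000_003 + cohort_index * 977) % (2**31)


def _simulate_study_cohort(
    config: HumanStudyConfig, n_case: int, n_control: int, cohort_index: int, prefix: str
) -> dict[str, SpectrumMatrix]:
    """Six-location cohort with subject-level loadings shared across locations."""
    sim = SyntheticCohortConfig(
        n_case=n_case,
        n_control=n_control,
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
        seed=_cohort_seed(config.seed, cohort_index),
    )
    matrices, _ = simulate_multisite_cohort(sim, locations=LOCATIONS)
    for matrix in matrices.values():
        matrix.subject_ids = [f"{prefix}{i:03d}" for i in range(matrix.n_subjects)]
    return matrices


def _score_table(models: dict[str, DropDModel], cohort: dict[str, SpectrumMatrix],
                 eye: str) -> HSScoreTable:
    rows = []
    for loc, matrix in cohort.items():
        s = score_matrix(models[loc], matrix)
        for sid, lab, val in zip(matrix.subject_ids, matrix.labels, s):
            rows.append({"subject_id": sid, "eye": eye, "location_id": loc,
                         "score": float(val), "label": lab})
    return aggregate_scores(HSScoreTable(frame=pd.DataFrame(rows)))


def run_human_study(config: HumanStudyConfig = HumanStudyConfig(),
                    out_dir: Optional[str | Path] = None) -> HumanStudyReport:
    """Run the full synthetic human study; optionally write the report bundle."""
    cohorts = {
        "principal": (config.n_case, config.n_control, 0, "P"),
        "fellow": (config.n_fellow_case, config.n_fellow_control, 1, "F"),
        "validation": (config.n_validation_case, config.n_validation_control, 2, "V"),
    }
    data: dict[str, dict[str, SpectrumMatrix]] = {
        name: _simulate_study_cohort(config, nc, nk, idx, prefix)
        for name, (nc, nk, idx, prefix) in cohorts.items()
    }

    # train on principal study eyes, one model per location, k by LOO
    models: dict[str, DropDModel] = {}
    cv_curves: dict[str, CvCurve] = {}
    for loc in LOCATIONS:
        cv = select_k_loocv(data["principal"][loc], k_max=config.k_max)
        cv_curves[loc] = cv
        models[loc] = fit_dropd(data["principal"][loc], cv.chosen_k)

    scores = {
        "principal": _score_table(models, data["principal"], eye="study"),
        "fellow": _score_table(models, data["fellow"], eye="fellow"),
        "validation": _score_table(models, data["validation"], eye="study"),
    }

    # location-wise t tests on the principal cohort, BY-corrected
    test_rows = []
    principal = scores["principal"].frame
    for loc in list(LOCATIONS) + ["overall"]:
        sub = principal[principal["location_id"] == loc]
        res = ttest_from_samples(
            sub.loc[sub["label"] == "control", "score"],
            sub.loc[sub["label"] == "case", "score"],
        )
        test_rows.append({"location_id": loc, "mean_diff": res.mean_diff,
                          "ci_low": res.ci_low, "ci_high": res.ci_high,
                          "t": res.t, "p": res.p})
    location_tests = pd.DataFrame(test_rows)
    fdr = by_fdr(location_tests["p"].to_numpy(), q=config.fdr_q)
    fdr_reject = dict(zip(location_tests["location_id"], map(bool, fdr.reject)))

    anova = rm_anova_group_effect(scores["principal"])

    roc = {}
    for name, table in scores.items():
        overall = table.frame[table.frame["location_id"] == "overall"]
        roc[name] = roc_auc(overall["score"].to_numpy(), overall["label"].to_numpy())

    # synthetic amyloid-burden covariate (PET-like): group-shifted noisy proxy
    rng = np.random.default_rng((config.seed * 1_000_003 + 7) % (2**31))
    overall = scores["principal"].frame.query("location_id == 'overall'").sort_values("subject_id")
    burden = (overall["label"] == "case").to_numpy(float) + rng.normal(0, 0.5, len(overall))
    pet_corr = pearson_corr(overall["score"].to_numpy(), burden)

    report = HumanStudyReport(
        config=config, models=models, cv_curves=cv_curves, scores=scores,
        location_tests=location_tests, fdr_reject=fdr_reject, anova=anova,
        roc=roc, pet_correlation=pet_corr,
    )
    if out_dir is not None:
        report.save(out_dir)
    return report
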