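"""Delimited-text readers and writers for the survey artefacts.

A survey directory contains households.csv, members.csv,
consumption.csv, composition.csv, adult_equivalents.csv and — for
synthetic data only — a truth.json sidecar with the generator's hidden
labels and true coefficients.  Column schemas are documented in
docs/schema.md.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .nutrition_scoring import AdultEquivalentTable
from .records import SurveyDataset, SurveyTruth

_BOOL_COLS = ["home_owned", "head_employed", "head_under_education", "head_married"]


def write_composition(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_composition(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"item_id", "kcal_per_100g", "waste_fraction", "grams_per_unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    return df


def write_ae_table(table: AdultEquivalentTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_ae_table(path: str | Path) -> AdultEquivalentTable:
    return AdultEquivalentTable.from_frame(pd.read_csv(path))


def write_survey(dataset: SurveyDataset, directory: str | Path) -> None:
    """Write a survey to a directory of CSVs (plus truth.json if the
    dataset is synthetic)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.households.to_csv(directory / "households.csv", index=False)
    dataset.members.to_csv(directory / "members.csv", index=False)
    dataset.consumption.to_csv(directory / "consumption.csv", index=False)
    dataset.composition.to_csv(directory / "composition.csv", index=False)
    if dataset.ae_table is not None:
        write_ae_table(dataset.ae_table, directory / "adult_equivalents.csv")
    if dataset.truth is not None:
        truth = {
            "predictor_names": dataset.truth.predictor_names,
            "coefficients": {str(r): list(map(float, v))
                             for r, v in dataset.truth.coefficients.items()},
            "labels": dataset.truth.labels.to_dict(orient="list"),
            "covariates": dataset.truth.covariates.to_dict(orient="list"),
        }
        (directory / "truth.json").write_text(json.dumps(truth))


def read_survey(directory: str | Path) -> SurveyDataset:
    """Read a survey directory; the truth sidecar is attached only if
    truth.json is present (real-format surveys have none)."""
    directory = Path(directory)
    households = pd.read_csv(directory / "households.csv")
    for col in _BOOL_COLS:
        if col in households.columns:
            households[col] = households[col].astype(bool)
    members = pd.read_csv(directory / "members.csv")
    consumption = pd.read_csv(directory / "consumption.csv")
    composition = read_composition(directory / "composition.csv")
    ae_path = directory / "adult_equivalents.csv"
    ae_table = read_ae_table(ae_path) if ae_path.exists() else None

    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        labels = pd.DataFrame(raw["labels"])
        labels["food_secure"] = labels["food_secure"].astype(bool)
        truth = SurveyTruth(
            coefficients={int(r): np.asarray(v, dtype=float)
                          for r, v in raw["coefficients"].items()},
            predictor_names=list(raw["predictor_names"]),
            labels=labels,
            covariates=pd.DataFrame(raw["covariates"]),
        )
    return SurveyDataset(households=households, members=members,
                         consumption=consumption, composition=composition,
                         ae_table=ae_table, truth=truth)


def write_model_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index=False)


def read_model_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_intake_results(intake: pd.DataFrame, path: str | Path) -> None:
    intake.to_csv(path, index=False)


def write_fits(fit_frames: dict[str, pd.DataFrame], path: str | Path) -> None:
    """One row per stratum x term: coefficient, SE, OR, p, stars."""
    rows = []
    for stratum, frame in fit_frames.items():
        f = frame.copy()
        f.insert(0, "stratum", stratum)
        rows.append(f)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
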