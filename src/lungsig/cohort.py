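"""Cohort and feature-table IO, matrix alignment, baseline statistics.

Tables are plain UTF-8 CSV with a header row and '.' decimals.  The
cohort schema is: patient_id, outcome (0 non-cancer / 1 lung cancer),
stage (blank or I..IV, present iff outcome = 1), age, sex, smoking,
split (blank / train / test).  Feature tables carry a patient_id column
plus named numeric covariates; each table belongs to one modality
(immune, dotblot, ctta, dla, score).

The baseline (Table-1 style) comparison uses an unpaired two-tailed
pooled-variance Student t-test for age and Pearson chi-square tests
without continuity correction for the categorical variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ("patient_id", "outcome", "stage", "age", "sex", "smoking", "split")
MODALITIES = ("immune", "dotblot", "ctta", "dla", "score")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    if cohort["patient_id"].duplicated().any():
        dups = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids: {dups[:5]}")
    if not cohort["outcome"].isin([0, 1]).all():
        raise ValueError("outcome must be 0 or 1")
    staged = cohort["stage"].fillna("").astype(str) != ""
    if (staged & (cohort["outcome"] == 0)).any():
        raise ValueError("stage present for a non-cancer patient")
    return cohort


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "stage": str, "split": str},
                     keep_default_na=False)
    df["outcome"] = df["outcome"].astype(int)
    df["age"] = df["age"].astype(float)
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort).to_csv(path, index=False)


def read_features(path: str | Path, modality: str) -> pd.DataFrame:
    """Feature CSV -> patient-indexed numeric DataFrame tagged with its modality."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: no patient_id column")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"{path}: duplicate patient ids {dups[:5]}")
    df = df.set_index("patient_id")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate feature columns")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric values in column {col!r}") from exc
    df.attrs["modality"] = modality
    return df


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    out = features.copy()
    out.index.name = "patient_id"
    out.to_csv(path)


def align(
    cohort: pd.DataFrame, *matrices: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Inner-join feature matrices on patient id against the cohort.

    Returns the joined matrix (stable column order, columns prefixed by
    modality on collision) and the aligned outcome vector.  Dropped ids
    are logged and recorded on ``X.attrs['dropped_ids']``.
    """
    validate_cohort(cohort)
    if not matrices:
        raise ValueError("no feature matrices given")
    ids = pd.Index(cohort["patient_id"])
    for m in matrices:
        ids = ids.intersection(m.index)
    if len(ids) == 0:
        raise ValueError("no overlapping patients across cohort and feature matrices")
    # keep cohort order
    ids = pd.Index([i for i in cohort["patient_id"] if i in set(ids)])

    all_ids = set(cohort["patient_id"])
    for m in matrices:
        all_ids |= set(m.index)
    dropped = sorted(all_ids - set(ids))
    if dropped:
        logger.warning("align: dropped %d ids without full coverage: %s",
                       len(dropped), dropped[:10])

    seen: dict[str, str] = {}
    parts = []
    for m in matrices:
        part = m.loc[ids]
        modality = m.attrs.get("modality", "feat")
        rename = {}
        for col in part.columns:
            if col in seen:
                rename[col] = f"{modality}:{col}"
            else:
                seen[col] = modality
        if rename:
            part = part.rename(columns=rename)
        parts.append(part)
    X = pd.concat(parts, axis=1)
    if X.columns.duplicated().any():
        raise ValueError("duplicate column names persist after modality prefixing")
    X.attrs["dropped_ids"] = dropped
    y = cohort.set_index("patient_id").loc[ids, "outcome"]
    return X, y


# ---------------------------------------------------------------------------
# baseline (Table-1 style) statistics


@dataclass
class BaselineRow:
    variable: str
    test: str
    statistic: float
    df: int
    p_value: float
    detail: pd.DataFrame


def chi2_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    keep_r = obs.sum(axis=1) > 0
    keep_c = obs.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("chi2: dropping zero-count rows/columns")
        obs = obs[keep_r][:, keep_c]
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def baseline_table(cohort: pd.DataFrame) -> dict[str, BaselineRow]:
    """Compare baseline variables between outcome groups.

    Age: pooled-variance Student t-test (two-tailed).  Sex, smoking and
    train/test split: Pearson chi-square without continuity correction.
    """
    validate_cohort(cohort)
    g0 = cohort[cohort["outcome"] == 0]
    g1 = cohort[cohort["outcome"] == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both outcome groups must be non-empty")

    rows: dict[str, BaselineRow] = {}
    t, p = stats.ttest_ind(g0["age"], g1["age"], equal_var=True)
    detail = pd.DataFrame(
        {
            "n": [len(g0), len(g1)],
            "mean": [g0["age"].mean(), g1["age"].mean()],
            "min": [g0["age"].min(), g1["age"].min()],
            "max": [g0["age"].max(), g1["age"].max()],
        },
        index=["non-cancer", "cancer"],
    )
    rows["age"] = BaselineRow("age", "t-test (pooled)", float(t),
                              len(g0) + len(g1) - 2, float(p), detail)

    for var in ("sex", "smoking", "split"):
        col = cohort[var].fillna("").astype(str)
        if var == "split" and (col == "").all():
            continue
        counts = pd.crosstab(col, cohort["outcome"])
        counts = counts.loc[counts.sum(axis=1) > 0]
        stat, dof, p = chi2_independence(counts.to_numpy())
        rows[var] = BaselineRow(var, "chi-square", stat, dof, p,
                                counts.rename(columns={0: "non-cancer", 1: "cancer"}))
    return rows


def baseline_report(rows: dict[str, BaselineRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"variable": r.variable, "test": r.test, "statistic": r.statistic,
             "df": r.df, "p_value": r.p_value}
            for r in rows.values()
        ]
    )
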