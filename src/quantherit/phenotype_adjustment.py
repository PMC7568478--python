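"""Per-examination age/sex adjustment and cross-exam residual averaging.

Within each examination stratum the phenotype is regressed (OLS) on
[1, female, age, age^2, female*age, female*age^2] and replaced by its
residual; each individual's adjusted value is then the mean of their
per-exam residuals.  Strata are (cohort, exam_id) when a cohort column
is present, else exam_id alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["adjust_exam", "average_residuals", "adjust_phenotypes", "raw_exam_means"]

DESIGN_COLUMNS = ("intercept", "female", "age", "age2", "female_age", "female_age2")

_MIN_RECORDS = 7  # six design parameters + 1


def _female_indicator(sex: pd.Series) -> np.ndarray:
    s = sex.astype(str).str.upper().str.strip()
    mapping = {"F": 1.0, "FEMALE": 1.0, "1": 1.0, "M": 0.0, "MALE": 0.0, "0": 0.0}
    unknown = sorted(set(s.unique()) - set(mapping))
    if unknown:
        raise ValidationError(f"unrecognised sex codes: {unknown}")
    return s.map(mapping).to_numpy(dtype=float)


def _design_matrix(age: np.ndarray, female: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [
            np.ones_like(age),
            female,
            age,
            age**2,
            female * age,
            female * age**2,
        ]
    )


def _check_full_rank(X: np.ndarray) -> None:
    """Raise naming the first column collinear with its predecessors."""
    for j in range(1, X.shape[1]):
        sub = X[:, : j + 1]
        if np.linalg.matrix_rank(sub) <= j:
            raise ValidationError(
                f"design is rank deficient: column {DESIGN_COLUMNS[j]!r} is "
                "collinear with earlier columns "
                "(e.g. a single sex or a single age in the stratum)"
            )


def adjust_exam(records: pd.DataFrame) -> pd.Series:
    """OLS age/sex residuals for one examination stratum.

    ``records`` needs columns value, age, sex.  Returns residuals
    aligned with the input index; they sum to zero up to numerical
    tolerance because the design contains an intercept.
    """
    for col in ("value", "age", "sex"):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    if len(records) < _MIN_RECORDS:
        raise ValidationError(
            f"need at least {_MIN_RECORDS} records per stratum, got {len(records)}"
        )
    y = records["value"].to_numpy(dtype=float)
    age = records["age"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("phenotype values must be finite")
    if np.any(age <= 0):
        raise ValidationError("ages must be positive")
    female = _female_indicator(records["sex"])
    if female.min() == female.max():
        raise ValidationError("both sexes must be represented in each stratum")
    X = _design_matrix(age, female)
    _check_full_rank(X)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return pd.Series(resid, index=records.index, name="residual")


def average_residuals(residuals: pd.DataFrame) -> pd.DataFrame:
    """Average per-exam residuals into one adjusted value per individual.

    ``residuals`` needs columns individual_id and residual.  Returns
    columns individual_id, adjusted_value, n_exams_used.
    """
    for col in ("individual_id", "residual"):
        if col not in residuals.columns:
            raise ValidationError(f"residuals missing column {col!r}")
    grouped = residuals.groupby("individual_id", sort=False)["residual"]
    out = grouped.agg(adjusted_value="mean", n_exams_used="size").reset_index()
    out["n_exams_used"] = out["n_exams_used"].astype(int)
    return out


def adjust_phenotypes(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full adjustment stage: per-stratum residuals, then per-individual means.

    ``phenotypes`` needs individual_id, exam_id, value plus age/sex
    (taken from ``pedigree`` when absent).  The stratum key is
    (cohort, exam_id) when a cohort column exists, else exam_id.
    """
    pheno = phenotypes.copy()
    needed = {"individual_id", "exam_id", "value"}
    missing = needed - set(pheno.columns)
    if missing:
        raise ValidationError(f"phenotypes missing columns {sorted(missing)}")
    if "age" not in pheno.columns or "sex" not in pheno.columns:
        if pedigree is None:
            raise ValidationError(
                "phenotypes lack age/sex columns and no pedigree was given"
            )
        pheno = pheno.merge(
            pedigree[["individual_id", "age", "sex"]], on="individual_id", how="left"
        )
        if pheno["age"].isna().any() or pheno["sex"].isna().any():
            orphans = pheno.loc[pheno["age"].isna(), "individual_id"].unique()
            raise ValidationError(
                f"phenotype rows with no pedigree entry: {list(orphans)[:5]}"
            )

    strata = ["cohort", "exam_id"] if "cohort" in pheno.columns else ["exam_id"]
    parts = []
    for _, stratum in pheno.groupby(strata, sort=False):
        resid = adjust_exam(stratum)
        parts.append(
            pd.DataFrame(
                {
                    "individual_id": stratum["individual_id"].to_numpy(),
                    "residual": resid.to_numpy(),
                }
            )
        )
    residuals = pd.concat(parts, ignore_index=True)
    return average_residuals(residuals)


def raw_exam_means(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-individual mean of unadjusted exam values (for the
    unadjusted-dependent analysis mode)."""
    grouped = phenotypes.groupby("individual_id", sort=False)["value"]
    out = grouped.mean().reset_index().rename(columns={"value": "raw_value"})
    return out
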