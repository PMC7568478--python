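"""Relative-pair construction with family-aware degrees of freedom.

Builds the weighted offspring-parent, offspring-midparent and
double-entry full-sib pair tables from a pedigree plus per-individual
adjusted phenotypes, together with the degrees-of-freedom accounting
(sum k_i - 2 for offspring-parent/midparent, sum (k_i - 1) for
sibships, k_i = offspring count in family i).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PedigreeError, ValidationError

__all__ = [
    "RelativePairSet",
    "build_offspring_parent",
    "build_midparent",
    "build_full_sib",
    "spouse_correlation",
]

PAIR_COLUMNS = ["family_id", "dependent_value", "predictor_value", "weight"]


@dataclass
class RelativePairSet:
    """A set of relative pairs with df bookkeeping.

    ``pairs`` has columns family_id, dependent_value, predictor_value,
    weight.  ``df`` follows the family-adjusted rules; ``n_excluded``
    counts offspring dropped for lack of a phenotyped relative.
    """

    pairs: pd.DataFrame
    pair_kind: str
    df: int
    n_families: int
    n_excluded: int = 0
    dependent_adjusted: bool = True

    def __post_init__(self):
        missing = [c for c in PAIR_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise ValidationError(f"pair table missing columns {missing}")
        if self.df < 0:
            raise ValidationError(f"degrees of freedom must be >= 0, got {self.df}")

    def __len__(self):
        return len(self.pairs)

    @property
    def meta(self) -> dict:
        return {
            "pair_kind": self.pair_kind,
            "df": int(self.df),
            "n_families": int(self.n_families),
            "n_pairs": int(len(self.pairs)),
            "n_excluded": int(self.n_excluded),
            "dependent_adjusted": bool(self.dependent_adjusted),
        }

    def write(self, path) -> None:
        """Write pairs.csv plus a JSON sidecar with df and counts."""
        path = Path(path)
        self.pairs.to_csv(path, index=False)
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def read(cls, path) -> "RelativePairSet":
        path = Path(path)
        pairs = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            pairs=pairs,
            pair_kind=meta["pair_kind"],
            df=meta["df"],
            n_families=meta["n_families"],
            n_excluded=meta.get("n_excluded", 0),
            dependent_adjusted=meta.get("dependent_adjusted", True),
        )


def _check_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    required = {"individual_id", "family_id", "father_id", "mother_id"}
    missing = required - set(pedigree.columns)
    if missing:
        raise ValidationError(f"pedigree missing columns {sorted(missing)}")
    if pedigree["individual_id"].duplicated().any():
        dup = pedigree.loc[pedigree["individual_id"].duplicated(), "individual_id"]
        raise PedigreeError(f"duplicate individual ids: {list(dup.unique())[:5]}")
    for col in ("father_id", "mother_id"):
        own = pedigree[col].notna() & (pedigree[col] == pedigree["individual_id"])
        if own.any():
            bad = pedigree.loc[own, "individual_id"].tolist()
            raise PedigreeError(f"individuals listed as their own parent: {bad[:5]}")
    return pedigree


def _value_map(adjusted: pd.DataFrame, column: str) -> pd.Series:
    if "individual_id" not in adjusted.columns or column not in adjusted.columns:
        raise ValidationError(
            f"adjusted table needs columns individual_id and {column}"
        )
    return adjusted.set_index("individual_id")[column]


def _offspring_table(pedigree, values):
    """Offspring rows annotated with their own and both parents' values."""
    ped = pedigree.copy()
    is_offspring = ped["father_id"].notna() | ped["mother_id"].notna()
    off = ped.loc[is_offspring].copy()
    off["own_value"] = off["individual_id"].map(values)
    off["father_value"] = off["father_id"].map(values)
    off["mother_value"] = off["mother_id"].map(values)
    return off


def _op_df(k_by_family: pd.Series) -> int:
    """Global sum(k_i) - 2 over families contributing pairs."""
    if k_by_family.empty:
        return 0
    return max(int(k_by_family.sum()) - 2, 0)


def build_offspring_parent(
    pedigree: pd.DataFrame,
    adjusted: pd.DataFrame,
    dependent_adjusted: bool = True,
    raw_values: pd.DataFrame | None = None,
) -> RelativePairSet:
    """Weighted offspring-parent pairs.

    One pair per available child-parent combination; each pair gets
    weight 1/2 when both parents are phenotyped and weight 1 when only
    one is.  Offspring without any phenotyped parent are excluded and
    counted.  When ``dependent_adjusted`` is False the dependent value
    is taken from ``raw_values`` (unadjusted exam-mean phenotype) while
    the parent predictor stays adjusted.
    """
    pedigree = _check_pedigree(pedigree)
    values = _value_map(adjusted, "adjusted_value")
    dep_values = values
    if not dependent_adjusted:
        if raw_values is None:
            raise ValidationError(
                "raw_values is required when dependent_adjusted=False"
            )
        dep_values = _value_map(raw_values, "raw_value")

    off = _offspring_table(pedigree, values)
    off["dependent"] = off["individual_id"].map(dep_values)
    off = off[off["dependent"].notna()]
    n_parents = off[["father_value", "mother_value"]].notna().sum(axis=1)
    excluded = int((n_parents == 0).sum())
    off = off.loc[n_parents > 0].copy()
    off["pair_weight"] = np.where(n_parents.loc[off.index] == 2, 0.5, 1.0)

    rows = []
    for parent_col in ("father_value", "mother_value"):
        sub = off.loc[off[parent_col].notna()]
        rows.append(
            pd.DataFrame(
                {
                    "family_id": sub["family_id"].to_numpy(),
                    "dependent_value": sub["dependent"].to_numpy(dtype=float),
                    "predictor_value": sub[parent_col].to_numpy(dtype=float),
                    "weight": sub["pair_weight"].to_numpy(dtype=float),
                }
            )
        )
    pairs = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=PAIR_COLUMNS)
    k = off.groupby("family_id").size()
    return RelativePairSet(
        pairs=pairs,
        pair_kind="offspring_parent",
        df=_op_df(k),
        n_families=int(k.size),
        n_excluded=excluded,
        dependent_adjusted=dependent_adjusted,
    )


def build_midparent(
    pedigree: pd.DataFrame,
    adjusted: pd.DataFrame,
    dependent_adjusted: bool = True,
    raw_values: pd.DataFrame | None = None,
) -> RelativePairSet:
    """Offspring-midparent pairs, restricted to families with both parents.

    The predictor is the mean of the two parents' adjusted values; every
    pair has weight 1.
    """
    pedigree = _check_pedigree(pedigree)
    values = _value_map(adjusted, "adjusted_value")
    dep_values = values
    if not dependent_adjusted:
        if raw_values is None:
            raise ValidationError(
                "raw_values is required when dependent_adjusted=False"
            )
        dep_values = _value_map(raw_values, "raw_value")

    off = _offspring_table(pedigree, values)
    off["dependent"] = off["individual_id"].map(dep_values)
    off = off[off["dependent"].notna()]
    n_parents = off[["father_value", "mother_value"]].notna().sum(axis=1)
    excluded = int((n_parents < 2).sum())
    off = off.loc[n_parents == 2].copy()
    pairs = pd.DataFrame(
        {
            "family_id": off["family_id"].to_numpy(),
            "dependent_value": off["dependent"].to_numpy(dtype=float),
            "predictor_value": (
                (off["father_value"] + off["mother_value"]) / 2.0
            ).to_numpy(dtype=float),
            "weight": 1.0,
        }
    )
    k = off.groupby("family_id").size()
    return RelativePairSet(
        pairs=pairs,
        pair_kind="offspring_midparent",
        df=_op_df(k),
        n_families=int(k.size),
        n_excluded=excluded,
        dependent_adjusted=dependent_adjusted,
    )


def build_full_sib(
    pedigree: pd.DataFrame,
    adjusted: pd.DataFrame,
    dependent_adjusted: bool = True,
    raw_values: pd.DataFrame | None = None,
) -> RelativePairSet:
    """Double-entry full-sib pairs: k(k-1) ordered pairs per sibship.

    Sibships share both parent ids (half-sibs are excluded); singleton
    sibships contribute no pairs but enter df as k - 1 = 0.
    df = sum over sibships of (k_i - 1).
    """
    pedigree = _check_pedigree(pedigree)
    values = _value_map(adjusted, "adjusted_value")
    dep_values = values
    if not dependent_adjusted:
        if raw_values is None:
            raise ValidationError(
                "raw_values is required when dependent_adjusted=False"
            )
        dep_values = _value_map(raw_values, "raw_value")

    off = _offspring_table(pedigree, values)
    off = off[off["father_id"].notna() & off["mother_id"].notna()]
    off = off[off["individual_id"].map(values).notna()].copy()
    off["dependent"] = off["individual_id"].map(dep_values)
    off = off[off["dependent"].notna()]

    rows = []
    df = 0
    n_sibships = 0
    for (_, _), sib in off.groupby(["father_id", "mother_id"], sort=False):
        k = len(sib)
        df += k - 1
        n_sibships += 1
        if k < 2:
            continue
        dep = sib["dependent"].to_numpy(dtype=float)
        pred = sib["individual_id"].map(values).to_numpy(dtype=float)
        fam = sib["family_id"].iloc[0]
        idx_a, idx_b = np.nonzero(~np.eye(k, dtype=bool))
        rows.append(
            pd.DataFrame(
                {
                    "family_id": fam,
                    "dependent_value": dep[idx_a],
                    "predictor_value": pred[idx_b],
                    "weight": 1.0,
                }
            )
        )
    pairs = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=PAIR_COLUMNS)
    )
    return RelativePairSet(
        pairs=pairs,
        pair_kind="full_sib",
        df=df,
        n_families=n_sibships,
        dependent_adjusted=dependent_adjusted,
    )


def spouse_correlation(pedigree: pd.DataFrame, adjusted: pd.DataFrame) -> float:
    """Pearson correlation of spouses' adjusted values (double-entered).

    Couples are the distinct (father_id, mother_id) combinations among
    offspring rows; both members must be phenotyped.  Double entry makes
    the estimate symmetric in spouse ordering.
    """
    pedigree = _check_pedigree(pedigree)
    values = _value_map(adjusted, "adjusted_value")
    off = pedigree[pedigree["father_id"].notna() & pedigree["mother_id"].notna()]
    couples = off[["father_id", "mother_id"]].drop_duplicates()
    a = couples["father_id"].map(values).to_numpy(dtype=float)
    b = couples["mother_id"].map(values).to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValidationError(
            f"need at least 3 phenotyped couples, got {a.size}"
        )
    u = np.concatenate([a, b])
    v = np.concatenate([b, a])
    return float(np.corrcoef(u, v)[0, 1])
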