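"""Q-Q remapping of group-specific quantile curves onto a common axis.

A curve fitted on one group's percentile grid is re-expressed at the
concentrations of a reference (typically combined-group) distribution:
reference percentile p maps to concentration c = Q_ref(p), which sits at
percentile F_group(c) of the group's own distribution, where the group's
curve is interpolated.  Points falling outside the group's fitted
5th-95th percentile support are masked, never extrapolated.

The empirical quantile function uses linear interpolation between
order statistics at plotting positions p_i = (i - 0.5)/n; the empirical
CDF is its inverse under the same rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "EmpiricalQuantileFunction",
    "RemappedCurve",
    "empirical_qf",
    "remap_curve",
    "group_difference",
]


class EmpiricalQuantileFunction:
    """Interpolated empirical quantile function and its CDF inverse."""

    def __init__(self, values):
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if np.unique(values).size < 2:
            raise ValidationError(
                "need at least 2 distinct values for a quantile function"
            )
        if values.size < 20:
            warnings.warn(
                f"only {values.size} values: tail quantiles will be unstable",
                stacklevel=3,
            )
        self.sorted_values = np.sort(values)
        n = values.size
        self.positions = (np.arange(1, n + 1) - 0.5) / n

    @property
    def n(self) -> int:
        return self.sorted_values.size

    def quantile(self, p):
        """Q(p): concentration at percentile fraction p (clamped at the ends)."""
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValidationError("percentiles must lie in [0, 1]")
        return np.interp(p, self.positions, self.sorted_values)

    def cdf(self, x):
        """F(x): percentile fraction of concentration x under the same rule."""
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.sorted_values, self.positions)

    __call__ = quantile


def empirical_qf(values) -> EmpiricalQuantileFunction:
    """Build the interpolated empirical quantile function of a sample."""
    return EmpiricalQuantileFunction(values)


@dataclass
class RemappedCurve:
    """A group curve re-expressed on a reference concentration axis.

    ``valid`` masks reference points whose concentration falls inside
    the group's fitted percentile support; values (and replicate
    columns) outside it are NaN.
    """

    ref_percentiles: np.ndarray
    concentrations: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    group_percentiles: np.ndarray
    replicates: np.ndarray | None = None

    @property
    def se(self):
        if self.replicates is None:
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.replicates, axis=0, ddof=1)

    def to_frame(self, group: str = "") -> pd.DataFrame:
        se = self.se
        return pd.DataFrame(
            {
                "ref_percentile": 100.0 * self.ref_percentiles,
                "concentration": self.concentrations,
                "group": group,
                "value": self.values,
                "se": se if se is not None else np.nan,
                "valid": self.valid,
            }
        )


def remap_curve(
    curve_taus,
    curve_values,
    group_qf: EmpiricalQuantileFunction,
    ref_qf: EmpiricalQuantileFunction,
    ref_percentiles=None,
    replicates=None,
) -> RemappedCurve:
    """Re-plot a percentile-indexed curve at reference concentrations.

    Parameters
    ----------
    curve_taus, curve_values : array-like
        The group's fitted curve on its own percentile grid (fractions).
    group_qf, ref_qf : EmpiricalQuantileFunction
        Quantile functions of the group's and the reference (combined)
        raw phenotype distributions.
    ref_percentiles : array-like, optional
        Reference grid (fractions); defaults to ``curve_taus``.
    replicates : ndarray (B, T), optional
        Bootstrap replicates of the curve, remapped with the same
        interpolation so pointwise SEs transfer to the new axis.
    """
    taus = np.asarray(curve_taus, dtype=float)
    vals = np.asarray(curve_values, dtype=float)
    if taus.shape != vals.shape:
        raise ValidationError("curve grid and values have different lengths")
    if np.any(np.diff(taus) <= 0):
        raise ValidationError("curve grid must be strictly increasing")
    ref_p = taus if ref_percentiles is None else np.asarray(ref_percentiles, float)

    conc = ref_qf.quantile(ref_p)
    group_p = group_qf.cdf(conc)
    valid = (group_p >= taus[0] - 1e-12) & (group_p <= taus[-1] + 1e-12)

    out = np.full(ref_p.shape, np.nan)
    out[valid] = np.interp(group_p[valid], taus, vals)
    reps_out = None
    if replicates is not None:
        replicates = np.asarray(replicates, dtype=float)
        if replicates.shape[1] != taus.size:
            raise ValidationError("replicate matrix does not match the curve grid")
        reps_out = np.full((replicates.shape[0], ref_p.size), np.nan)
        for b in range(replicates.shape[0]):
            reps_out[b, valid] = np.interp(group_p[valid], taus, replicates[b])
    return RemappedCurve(
        ref_percentiles=ref_p,
        concentrations=conc,
        values=out,
        valid=valid,
        group_percentiles=group_p,
        replicates=reps_out,
    )


@dataclass
class GroupDifference:
    """Pointwise group contrast on a shared grid."""

    grid: np.ndarray
    difference: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    valid: np.ndarray
    df: int
    matching: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.grid,
                "difference": self.difference,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "valid": self.valid,
            }
        )


def _se_from_replicates(replicates):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(np.asarray(replicates, dtype=float), axis=0, ddof=1)


def group_difference(
    grid_a,
    values_a,
    grid_b,
    values_b,
    replicates_a,
    replicates_b,
    df_a: int,
    df_b: int,
    matching: str = "percentile",
) -> GroupDifference:
    """Pointwise A - B difference with independent-sample SEs.

    Both curves must be evaluated on the identical grid (percentiles or
    concentrations, stated by ``matching``); mismatched grids are an
    error, never silently re-gridded.  SE = sqrt(SE_A^2 + SE_B^2), t and
    two-sided p on df_a + df_b degrees of freedom.  Points where either
    curve is masked (NaN) are invalid.
    """
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if grid_a.shape != grid_b.shape or not np.allclose(grid_a, grid_b, atol=1e-12):
        raise ValidationError("group grids do not match; refusing to re-grid")
    if matching not in ("percentile", "concentration"):
        raise ValidationError(f"unknown matching mode {matching!r}")
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    se_a = _se_from_replicates(replicates_a)
    se_b = _se_from_replicates(replicates_b)
    diff = va - vb
    se = np.sqrt(se_a**2 + se_b**2)
    valid = np.isfinite(diff) & np.isfinite(se) & (se >= 0)
    df = int(df_a) + int(df_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~valid] = np.nan
    t = np.where(valid, t, np.nan)
    return GroupDifference(
        grid=grid_a,
        difference=diff,
        se=se,
        t=t,
        p=p,
        valid=valid,
        df=df,
        matching=matching,
    )
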