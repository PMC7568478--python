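"""Orthogonal-polynomial trend tests across the quantile grid.

Tests whether a slope (or heritability) curve is constant versus
linear/quadratic/cubic in the *percentile* of the trait distribution.
Contrasts are built by Gram-Schmidt orthogonalisation of the percentile
powers against the constant and against each other, then scaled so the
degree-d coefficient reads as "per one-percent increase" raised to the
corresponding power (the linear coefficient of a curve
beta = c * percentile + const is exactly c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NumericalError, ValidationError

__all__ = ["DEGREE_NAMES", "TrendTestResult", "orthogonal_contrasts", "trend_test"]

DEGREE_NAMES = ("linear", "quadratic", "cubic")


def orthogonal_contrasts(taus, max_degree: int = 3) -> np.ndarray:
    """Contrast vectors for polynomial trend in the percentile.

    Returns an array of shape (max_degree, T).  Row d-1 is orthogonal to
    the constant and to every lower-degree contrast, and satisfies
    ``contrast @ percentile**d == 1`` so that applied to an exactly
    degree-d polynomial curve it returns that curve's leading
    coefficient in per-percentile units.
    """
    taus = np.asarray(taus, dtype=float)
    if max_degree < 1:
        raise ValidationError("max_degree must be >= 1")
    if np.unique(taus).size < max_degree + 1:
        raise ValidationError(
            f"need at least {max_degree + 1} distinct taus for degree {max_degree}"
        )
    p = 100.0 * taus  # percentile scale
    T = p.size
    basis = [np.ones(T) / np.sqrt(T)]
    contrasts = np.empty((max_degree, T))
    for d in range(1, max_degree + 1):
        v = p**d
        for q in basis:
            v = v - (q @ v) * q
        norm = np.linalg.norm(v)
        if norm < 1e-10 * np.linalg.norm(p**d):
            raise ValidationError(
                f"tau grid is degenerate: percentile^{d} is collinear "
                "with lower-degree terms"
            )
        q = v / norm
        basis.append(q)
        scale = q @ (p**d)
        contrasts[d - 1] = q / scale
    return contrasts


@dataclass
class TrendTestResult:
    """Per-degree trend coefficients, SEs, t statistics and p-values."""

    degrees: tuple
    estimates: np.ndarray
    ses: np.ndarray
    ts: np.ndarray
    ps: np.ndarray
    df: int
    contrasts: np.ndarray

    def __getitem__(self, degree: str) -> dict:
        i = self.degrees.index(degree)
        return {
            "estimate": float(self.estimates[i]),
            "se": float(self.ses[i]),
            "t": float(self.ts[i]),
            "p": float(self.ps[i]),
        }

    def to_dict(self) -> dict:
        return {
            deg: self[deg] for deg in self.degrees
        } | {"df": int(self.df)}


def trend_test(
    curve,
    taus=None,
    vcov=None,
    replicates=None,
    df=None,
    max_degree: int = 3,
    contrasts=None,
) -> TrendTestResult:
    """Test a curve over the tau grid for polynomial trend.

    Parameters
    ----------
    curve : array-like or QuantileSlopeSet or HeritabilityCurve
        Values on the tau grid.  When a slope set / heritability curve
        is passed, its taus, replicates and df are used automatically.
    vcov : ndarray, optional
        Covariance of the curve values; derived from ``replicates`` when
        absent.  One of the two must be available.
    df : int
        Degrees of freedom for the t reference distribution.
    """
    values, taus, vcov, replicates, df = _unpack(curve, taus, vcov, replicates, df)
    if vcov is None and replicates is None:
        raise ValidationError("trend_test needs a vcov or a replicate matrix")
    if vcov is None:
        finite = np.all(np.isfinite(replicates), axis=1)
        if finite.sum() < 3:
            raise NumericalError("too few valid replicates for a covariance")
        vcov = np.cov(replicates[finite], rowvar=False, ddof=1)
    if df is None:
        raise ValidationError("trend_test needs degrees of freedom")
    if contrasts is None:
        contrasts = orthogonal_contrasts(taus, max_degree)
    contrasts = np.asarray(contrasts, dtype=float)
    if contrasts.shape[1] != values.size:
        raise ValidationError("contrast length does not match the tau grid")

    ests = contrasts @ values
    variances = np.einsum("ij,jk,ik->i", contrasts, vcov, contrasts)
    ses = np.sqrt(np.clip(variances, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(ses > 0, ests / ses, 0.0)
    ps = 2.0 * stats.t.sf(np.abs(ts), df)
    names = DEGREE_NAMES[: contrasts.shape[0]]
    return TrendTestResult(
        degrees=tuple(names),
        estimates=ests,
        ses=ses,
        ts=ts,
        ps=ps,
        df=int(df),
        contrasts=contrasts,
    )


def _unpack(curve, taus, vcov, replicates, df):
    # duck-typed: QuantileSlopeSet exposes .slopes, HeritabilityCurve .h2
    if hasattr(curve, "slopes"):
        values = np.asarray(curve.slopes, dtype=float)
        taus = curve.taus if taus is None else taus
        vcov = curve.vcov if vcov is None else vcov
        replicates = curve.boot_replicates if replicates is None else replicates
        df = curve.df if df is None else df
    elif hasattr(curve, "h2"):
        values = np.asarray(curve.h2, dtype=float)
        taus = curve.taus if taus is None else taus
        replicates = curve.replicates if replicates is None else replicates
        df = curve.df if df is None else df
    else:
        values = np.asarray(curve, dtype=float)
        if taus is None:
            raise ValidationError("taus are required for a bare value array")
    taus = np.asarray(taus, dtype=float)
    if values.shape != taus.shape:
        raise ValidationError("curve and tau grid lengths differ")
    return values, taus, vcov, replicates, df
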