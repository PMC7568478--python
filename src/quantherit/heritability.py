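"""Falconer transforms: regression slopes -> narrow-sense heritability.

Offspring on single parent:   h2 = 2*beta / (1 + r_spouse)
Offspring on midparent:       h2 = beta
Full sibs (double entry):     h2 = (sqrt(1 + 8*r_spouse*beta) - 1) / (2*r_spouse)

with the analytic limit h2 -> 2*beta as r_spouse -> 0 for the full-sib
form.  ``h2_curve`` maps a whole quantile-slope set (point estimates and
every bootstrap replicate), so the reported standard errors are the
replicate standard deviations of the transformed quantity; a
delta-method SE is carried alongside for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError
from .quantile_slopes import QuantileSlopeSet

__all__ = [
    "RELATIONSHIPS",
    "HeritabilityCurve",
    "h2_from_op",
    "h2_from_midparent",
    "h2_from_fs",
    "fs_slope_from_h2",
    "h2_curve",
]

RELATIONSHIPS = ("offspring_parent", "offspring_midparent", "full_sib")

_R_TINY = 1e-8  # below this, use the r -> 0 series limit of the full-sib form


def h2_from_op(beta_op: float, r_spouse: float) -> float:
    """Heritability from an offspring-(single-)parent slope."""
    if r_spouse <= -1:
        raise ValidationError(f"r_spouse must exceed -1, got {r_spouse}")
    return 2.0 * beta_op / (1.0 + r_spouse)


def h2_from_midparent(beta_om: float) -> float:
    """Heritability from the offspring-midparent slope (identity map)."""
    return float(beta_om)


def h2_from_fs(beta_fs: float, r_spouse: float) -> float:
    """Heritability from a double-entry full-sib slope.

    Solves h2/2 + r*h2^2/2 = beta for h2; for |r| below 1e-8 returns the
    series limit 2*beta.
    """
    if abs(r_spouse) < _R_TINY:
        return 2.0 * float(beta_fs)
    disc = 1.0 + 8.0 * r_spouse * beta_fs
    if disc < 0:
        raise NumericalError(
            "full-sib heritability undefined: 1 + 8*r*beta = "
            f"{disc:g} < 0 (beta={beta_fs}, r={r_spouse})"
        )
    return (np.sqrt(disc) - 1.0) / (2.0 * r_spouse)


def fs_slope_from_h2(h2: float, r_spouse: float) -> float:
    """Algebraic inverse of :func:`h2_from_fs`: beta = h2/2 + r*h2^2/2."""
    return h2 / 2.0 + r_spouse * h2 * h2 / 2.0


def _h2_fs_array(betas, r_spouse):
    """Vectorised full-sib transform; negative discriminants become NaN."""
    betas = np.asarray(betas, dtype=float)
    if abs(r_spouse) < _R_TINY:
        return 2.0 * betas, np.zeros(betas.shape, dtype=bool)
    disc = 1.0 + 8.0 * r_spouse * betas
    invalid = disc < 0
    out = np.full(betas.shape, np.nan)
    ok = ~invalid
    out[ok] = (np.sqrt(disc[ok]) - 1.0) / (2.0 * r_spouse)
    return out, invalid


@dataclass
class HeritabilityCurve:
    """Quantile-specific h2 with bootstrap and delta-method SEs.

    ``undefined`` flags point estimates with a negative full-sib
    discriminant; ``replicates`` holds the transformed bootstrap matrix
    (NaN where a replicate was invalid).
    """

    taus: np.ndarray
    h2: np.ndarray
    se: np.ndarray
    se_delta: np.ndarray
    replicates: np.ndarray
    relationship: str
    r_spouse: float
    df: int
    undefined: np.ndarray
    n_invalid_replicates: int = 0

    def tau_index(self, tau):
        idx = np.nonzero(np.isclose(self.taus, tau, atol=1e-9))[0]
        if idx.size == 0:
            raise ValidationError(f"tau={tau} is not on the fitted grid")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": self.taus,
                "h2": self.h2,
                "se": self.se,
                "se_delta": self.se_delta,
                "relationship": self.relationship,
                "r_spouse": self.r_spouse,
            }
        )

    def out_of_bounds(self) -> np.ndarray:
        """Mask of estimates outside [0, 1] (warned about, never clipped)."""
        with np.errstate(invalid="ignore"):
            return (self.h2 < 0) | (self.h2 > 1)


def h2_curve(
    slope_set: QuantileSlopeSet,
    relationship: str,
    r_spouse: float,
    max_invalid_frac: float = 0.01,
) -> HeritabilityCurve:
    """Transform a quantile-slope set into a heritability curve.

    The relationship's Falconer transform is applied to every point
    estimate and every bootstrap replicate; SE(tau) is the standard
    deviation of the transformed replicates, with the linearised
    (delta-method) SE reported alongside.  ``r_spouse`` is treated as a
    fixed plug-in constant.
    """
    if relationship not in RELATIONSHIPS:
        raise ValidationError(
            f"relationship must be one of {RELATIONSHIPS}, got {relationship!r}"
        )
    if r_spouse <= -1 or r_spouse >= 1:
        raise ValidationError(f"r_spouse must be in (-1, 1), got {r_spouse}")

    betas = slope_set.slopes
    reps = slope_set.boot_replicates
    beta_se = slope_set.boot_se
    n_invalid = 0
    undefined = np.zeros(betas.shape, dtype=bool)

    if relationship == "offspring_parent":
        factor = 2.0 / (1.0 + r_spouse)
        h2 = factor * betas
        reps_t = factor * reps
        se_delta = factor * beta_se
    elif relationship == "offspring_midparent":
        h2 = betas.copy()
        reps_t = reps.copy()
        se_delta = beta_se.copy()
    else:
        h2, undefined = _h2_fs_array(betas, r_spouse)
        reps_t, invalid = _h2_fs_array(reps, r_spouse)
        n_invalid = int(invalid.sum())
        if n_invalid > max_invalid_frac * reps.size:
            raise NumericalError(
                f"{n_invalid} of {reps.size} full-sib bootstrap replicates "
                "have a negative discriminant"
            )
        if abs(r_spouse) < _R_TINY:
            se_delta = 2.0 * beta_se
        else:
            with np.errstate(invalid="ignore"):
                se_delta = 2.0 / np.sqrt(1.0 + 8.0 * r_spouse * betas) * beta_se

    with np.errstate(invalid="ignore"):
        se = np.nanstd(reps_t, axis=0, ddof=1)
        n_oob = int(np.sum((np.asarray(h2) < 0) | (np.asarray(h2) > 1)))
    if n_oob:
        warnings.warn(
            f"{n_oob} heritability estimate(s) fall outside [0, 1]; the "
            "estimator can exceed its bounds on noisy data",
            stacklevel=2,
        )
    return HeritabilityCurve(
        taus=slope_set.taus.copy(),
        h2=np.asarray(h2, dtype=float),
        se=se,
        se_delta=np.asarray(se_delta, dtype=float),
        replicates=reps_t,
        relationship=relationship,
        r_spouse=float(r_spouse),
        df=slope_set.df,
        undefined=undefined,
        n_invalid_replicates=n_invalid,
    )
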