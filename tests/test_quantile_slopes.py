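import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quantherit import (
    NumericalError,
    ValidationError,
    check_loss,
    qreg_fit,
    slope_contrast,
    sqreg,
)
from quantherit.family_structures import RelativePairSet
from quantherit.quantile_slopes import DEFAULT_TAUS

from conftest import TAUS9


def brute_force_qreg(x, y, w, tau):
    """Independent oracle: enumerate all lines through two data points
    (an optimal LP basic solution interpolates two points) and return the
    minimal check loss with its line."""
    best = (np.inf, None)
    for i, j in itertools.combinations(range(len(x)), 2):
        if x[i] == x[j]:
            continue
        b = (y[j] - y[i]) / (x[j] - x[i])
        a = y[i] - b * x[i]
        obj = check_loss(y - a - b * x, tau, w)
        if obj < best[0]:
            best = (obj, (a, b))
    return best


def make_pairs(x, y, w=None, df=None):
    n = len(x)
    return RelativePairSet(
        pairs=pd.DataFrame(
            {
                "family_id": np.arange(n),
                "dependent_value": y,
                "predictor_value": x,
                "weight": np.ones(n) if w is None else w,
            }
        ),
        pair_kind="offspring_parent",
        df=n - 2 if df is None else df,
        n_families=n,
    )


class TestQregFit:
    @pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("method", ["exact", "mm"])
    def test_exact_line_recovered(self, tau, method):
        x = np.linspace(-2, 3, 25)
        fit = qreg_fit(x, 2.0 * x, tau, method=method)
        assert fit.slope == pytest.approx(2.0, abs=1e-5)
        assert fit.intercept == pytest.approx(0.0, abs=1e-5)
        assert fit.objective == pytest.approx(0.0, abs=1e-6)

    def test_three_point_example_matches_enumeration(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 4.0])
        fit = qreg_fit(x, y, 0.5)
        best_obj, (a, b) = brute_force_qreg(x, y, np.ones(3), 0.5)
        assert fit.objective == pytest.approx(best_obj, abs=1e-10)
        # the minimizing line interpolates two of the three points
        resid = y - fit.intercept - fit.slope * x
        assert np.sum(np.isclose(resid, 0.0, atol=1e-9)) >= 2

    def test_weight_doubling_leaves_fit_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40)
        w = rng.uniform(0.5, 2.0, size=40)
        f1 = qreg_fit(x, y, 0.25, weights=w)
        f2 = qreg_fit(x, y, 0.25, weights=2.0 * w)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-8)
        assert f2.intercept == pytest.approx(f1.intercept, abs=1e-8)
        assert f2.objective == pytest.approx(2.0 * f1.objective, rel=1e-10)

    def test_duplicating_pairs_equals_doubled_weights(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        f1 = qreg_fit(np.tile(x, 2), np.tile(y, 2), 0.75)
        f2 = qreg_fit(x, y, 0.75)
        assert f1.objective == pytest.approx(2.0 * f2.objective, rel=1e-9)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_lp_matches_brute_force_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        w = rng.uniform(0.5, 1.5, size=n)
        for tau in (0.25, 0.5, 0.75):
            fit = qreg_fit(x, y, tau, weights=w)
            best_obj, _ = brute_force_qreg(x, y, w, tau)
            assert fit.objective <= best_obj + 1e-8
            assert fit.objective >= best_obj - 1e-8

    def test_mm_agrees_with_exact(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        y = 0.3 * x + rng.standard_t(4, size=400)
        for tau in (0.1, 0.5, 0.9):
            fe = qreg_fit(x, y, tau, method="exact")
            fm = qreg_fit(x, y, tau, method="mm")
            assert fm.objective <= fe.objective * (1 + 1e-6)
            assert fm.slope == pytest.approx(fe.slope, abs=1e-3)

    @settings(max_examples=25, deadline=None)
    @given(
        cy=st.floats(0.1, 10.0),
        cx=st.floats(0.1, 10.0),
        dy=st.floats(-5.0, 5.0),
        dx=st.floats(-5.0, 5.0),
    )
    def test_equivariance(self, cy, cx, dy, dx):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        base = qreg_fit(x, y, 0.5)
        scaled = qreg_fit(cx * x + dx, cy * y + dy, 0.5)
        assert scaled.slope == pytest.approx(base.slope * cy / cx, rel=1e-6, abs=1e-9)
        expected_intercept = cy * base.intercept + dy - scaled.slope * dx
        assert scaled.intercept == pytest.approx(expected_intercept, rel=1e-6, abs=1e-7)

    def test_validation(self):
        x = np.arange(5.0)
        with pytest.raises(ValidationError):
            qreg_fit(x, x, 0.0)
        with pytest.raises(ValidationError):
            qreg_fit(np.ones(5), x, 0.5)  # constant predictor
        with pytest.raises(ValidationError):
            qreg_fit(x[:2], x[:2], 0.5)
        with pytest.raises(ValidationError):
            qreg_fit(x, x, 0.5, weights=np.zeros(5))


class TestSqreg:
    def test_well_posed_on_noisy_data(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=600)
        y = 0.5 * x + rng.normal(size=600)
        qs = sqreg(make_pairs(x, y), taus=TAUS9, B=60, seed=1)
        assert qs.taus.size == 9
        assert np.all(np.diag(qs.vcov) > 0)
        for tau in (0.10, 0.25, 0.50, 0.75, 0.90):
            qs.tau_index(tau)

    def test_default_grid_has_91_points(self):
        assert DEFAULT_TAUS.size == 91
        assert DEFAULT_TAUS[0] == 0.05 and DEFAULT_TAUS[-1] == 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = 0.4 * x + rng.normal(size=300)
        a = sqreg(make_pairs(x, y), taus=TAUS9, B=60, seed=7)
        b = sqreg(make_pairs(x, y), taus=TAUS9, B=60, seed=7)
        assert np.array_equal(a.boot_replicates, b.boot_replicates)
        assert np.array_equal(a.slopes, b.slopes)

    def test_family_bootstrap_keeps_families_together(self):
        # families with 2 pairs each and strong within-family dependence:
        # family resampling must give larger SEs than observation resampling
        rng = np.random.default_rng(6)
        n_fam = 300
        fam_effect = rng.normal(size=n_fam)
        x = np.repeat(rng.normal(size=n_fam), 2)
        y = 0.3 * x + np.repeat(fam_effect, 2) * 1.5 + 0.1 * rng.normal(size=2 * n_fam)
        pairs = RelativePairSet(
            pairs=pd.DataFrame(
                {
                    "family_id": np.repeat(np.arange(n_fam), 2),
                    "dependent_value": y,
                    "predictor_value": x,
                    "weight": 0.5,
                }
            ),
            pair_kind="offspring_parent",
            df=n_fam - 2,
            n_families=n_fam,
        )
        fam = sqreg(pairs, taus=TAUS9, B=150, seed=2, unit="family")
        obs = sqreg(pairs, taus=TAUS9, B=150, seed=2, unit="observation")
        i = fam.tau_index(0.5)
        assert fam.boot_se[i] > obs.boot_se[i]

    def test_grid_validation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        pairs = make_pairs(x, x + rng.normal(size=100))
        with pytest.raises(ValidationError, match="headline"):
            sqreg(pairs, taus=[0.2, 0.4, 0.6, 0.8], B=60)
        with pytest.raises(ValidationError, match="increasing"):
            sqreg(pairs, taus=[0.5, 0.25, 0.75, 0.10, 0.90], B=60)
        with pytest.raises(ValidationError, match="B must be"):
            sqreg(pairs, taus=TAUS9, B=10)

    def test_exact_engine_matches_mm_point_estimates(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=150)
        y = 0.6 * x + rng.normal(size=150)
        pairs = make_pairs(x, y)
        taus = np.array([0.10, 0.25, 0.50, 0.75, 0.90])
        a = sqreg(pairs, taus=taus, B=50, seed=3, engine="exact")
        b = sqreg(pairs, taus=taus, B=50, seed=3, engine="mm")
        assert np.allclose(a.slopes, b.slopes, atol=2e-3)

    def test_bivariate_normal_slope_curve_is_flat(self):
        rng = np.random.default_rng(9)
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(0.75) * rng.normal(size=n)
        qs = sqreg(make_pairs(x, y), taus=TAUS9, B=100, seed=4)
        mid = qs.tau_index(0.5)
        for i in range(qs.taus.size):
            se = np.sqrt(qs.vcov[i, i] + qs.vcov[mid, mid] - 2 * qs.vcov[i, mid])
            if i != mid:
                assert abs(qs.slopes[i] - qs.slopes[mid]) < 4 * max(se, 1e-9)

    def test_lognormal_slopes_increase(self):
        rng = np.random.default_rng(10)
        n = 4000
        zx = rng.normal(size=n)
        zy = 0.5 * zx + np.sqrt(0.75) * rng.normal(size=n)
        qs = sqreg(make_pairs(np.exp(zx), np.exp(zy)), taus=TAUS9, B=100, seed=5)
        c = np.zeros(qs.taus.size)
        c[qs.tau_index(0.90)] = 1.0
        c[qs.tau_index(0.10)] = -1.0
        res = slope_contrast(qs, c)
        assert res.estimate > 0
        assert res.estimate > 3 * res.se


class TestSlopeContrast:
    def fit(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        return sqreg(make_pairs(x, y), taus=TAUS9, B=60, seed=6)

    def test_unit_contrast_returns_slope_and_se(self):
        qs = self.fit()
        c = np.zeros(qs.taus.size)
        i = qs.tau_index(0.5)
        c[i] = 1.0
        res = slope_contrast(qs, c)
        assert res.estimate == pytest.approx(qs.slopes[i])
        assert res.se == pytest.approx(qs.boot_se[i])
        assert res.df == qs.df

    def test_zero_contrast(self):
        qs = self.fit()
        res = slope_contrast(qs, np.zeros(qs.taus.size))
        assert res.estimate == 0.0
        assert res.se == 0.0

    def test_length_mismatch(self):
        qs = self.fit()
        with pytest.raises(ValidationError):
            slope_contrast(qs, np.ones(3))

    def test_non_psd_vcov_rejected(self):
        qs = self.fit()
        qs.vcov = qs.vcov.copy()
        qs.vcov[0, 0] = -1.0
        with pytest.raises(NumericalError):
            slope_contrast(qs, np.ones(qs.taus.size))
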