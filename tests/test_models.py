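"""Chained regressions: OLS core, models 1-3, absolute explained variance."""

import numpy as np
import pytest

from gaitstab import (
    absolute_explained_variance,
    fit_ankle_strategy_model,
    fit_foot_placement_model,
    fit_muscle_model,
    ols_no_intercept,
)
from gaitstab.exceptions import CollinearityError, InsufficientDataError
from gaitstab.kinematics import StepTable
from gaitstab.models import FootPlacementFit


def _make_table(rng, n=200, beta_pos=0.5, beta_vel=0.2, sigma_fp=0.007,
                cop=None, emg=None):
    """StepTable with the generative latent structure, fully in memory."""
    p = 0.015 * rng.standard_normal(n)
    q = 0.008 * rng.standard_normal(n)
    g = np.exp(-2.5 * np.linspace(0, 0.5, 51))
    com_pos = p[:, None] + q[:, None] * g[None, :]
    com_vel = -2.5 * q[:, None] * g[None, :]
    e = sigma_fp * rng.standard_normal(n)
    fp = beta_pos * com_pos[:, 0] + beta_vel * com_vel[:, 0] + e
    demean = lambda a: a - a.mean(axis=0)
    return StepTable(
        side=np.array(["left", "right"] * (n // 2)),
        stride_index=np.arange(n),
        fp=demean(fp),
        com_pos=demean(com_pos),
        com_vel=demean(com_vel),
        cop_shift=demean(cop if cop is not None else rng.standard_normal(n) * 0.006),
        emg=None if emg is None else demean(emg),
    ), e


# ------------------------------------------------------------------ OLS ----

def test_ols_exact_fit_and_null_fit(rng):
    X = rng.standard_normal((50, 2))
    beta = np.array([1.5, -0.7])
    coef, resid, fitted, r2 = ols_no_intercept(X @ beta, X)
    np.testing.assert_allclose(coef, beta, atol=1e-12)
    assert np.abs(resid).max() < 1e-12 and r2 == pytest.approx(1.0)
    # y orthogonal to the design -> zero coefficients, zero r2
    q, _ = np.linalg.qr(rng.standard_normal((50, 3)))
    coef, _, _, r2 = ols_no_intercept(q[:, 2], q[:, :2])
    np.testing.assert_allclose(coef, 0.0, atol=1e-12)
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_ols_matches_normal_equations_oracle(rng):
    for _ in range(10):
        n, p = int(rng.integers(10, 100)), int(rng.integers(1, 5))
        X, y = rng.standard_normal((n, p)), rng.standard_normal(n)
        coef, _, _, _ = ols_no_intercept(y, X)
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(coef - ref)) <= 1e-8 * max(np.abs(ref).max(), 1e-12)


def test_ols_error_conditions(rng):
    X = rng.standard_normal((20, 2))
    X[:, 1] = 2 * X[:, 0]
    with pytest.raises(CollinearityError):
        ols_no_intercept(rng.standard_normal(20), X)
    with pytest.raises(InsufficientDataError):
        ols_no_intercept(np.ones(2), rng.standard_normal((2, 2)))
    with pytest.raises(InsufficientDataError):
        ols_no_intercept(np.zeros(20), rng.standard_normal((20, 1)))


# -------------------------------------------------------------- model 1 ----

def test_foot_placement_gains_recovered_noise_free(rng):
    table, _ = _make_table(rng, sigma_fp=0.0)
    fit = fit_foot_placement_model(table)
    np.testing.assert_allclose(fit.beta_pos, 0.5, atol=1e-6)
    np.testing.assert_allclose(fit.beta_vel, 0.2, atol=1e-6)
    np.testing.assert_allclose(fit.error_fp, 0.0, atol=1e-9)
    # residuals orthogonal to both predictors at every index
    for i in range(0, 51, 10):
        assert abs(fit.error_fp[:, i] @ table.com_pos[:, i]) < 1e-10
        assert abs(fit.error_fp[:, i] @ table.com_vel[:, i]) < 1e-10


def test_fp_independent_of_com_state_gives_null_r2(rng):
    table, _ = _make_table(rng, beta_pos=0.0, beta_vel=0.0, sigma_fp=0.01)
    fit = fit_foot_placement_model(table)
    assert np.all(fit.r2 <= 2 / np.sqrt(len(table)))


def test_lateral_misstep_yields_positive_error(rng):
    """Adding +1 cm to one step's placement makes its residual ~ +1 cm."""
    table, _ = _make_table(rng, sigma_fp=0.0)
    table.fp[7] += 0.01
    table.fp -= table.fp.mean()
    fit = fit_foot_placement_model(table)
    assert fit.error_fp[7, 24] > 0.009   # positive = too lateral


# -------------------------------------------------------------- model 2 ----

def _fit1_from(table, rng=None):
    return fit_foot_placement_model(table)


def test_ankle_strategy_exact_and_null(rng):
    table, e = _make_table(rng, sigma_fp=0.007)
    table.cop_shift = -0.3 * (e - e.mean())
    fit1 = _fit1_from(table)
    fit2 = fit_ankle_strategy_model(table, fit1, i_used=25)
    assert fit2.beta_error == pytest.approx(-0.3, rel=1e-6)
    assert fit2.r2 > 0.97   # model 1 absorbs the predictor-collinear share
    # null: cop shift independent of the error
    table.cop_shift = 0.006 * rng.standard_normal(len(table))
    table.cop_shift -= table.cop_shift.mean()
    null = fit_ankle_strategy_model(table, fit1, i_used=51)
    assert abs(null.beta_error) < 0.3
    assert null.aev < 0.15  # cm


def test_ankle_strategy_subsets_agree_for_symmetric_generator(rng):
    table, e = _make_table(rng, n=600)
    table.cop_shift = -0.3 * (e - e.mean()) + 0.004 * rng.standard_normal(600)
    table.cop_shift -= table.cop_shift.mean()
    fit1 = _fit1_from(table)
    med = fit_ankle_strategy_model(table, fit1, 25, subset="medial_only")
    lat = fit_ankle_strategy_model(table, fit1, 25, subset="lateral_only")
    assert med.n_steps + lat.n_steps == len(table)
    assert med.beta_error == pytest.approx(lat.beta_error, abs=0.15)
    with pytest.raises(ValueError):
        fit_ankle_strategy_model(table, fit1, i_used=26)


# -------------------------------------------------------------- model 3 ----

def test_muscle_model_signs_and_oracle(rng):
    n = 400
    emg = rng.standard_normal((n, 3)) * 0.1
    gains = np.array([-0.005, 0.003, 0.003])      # m per scalar unit
    cop = emg @ gains + 0.0005 * rng.standard_normal(n)
    table, _ = _make_table(rng, n=n, cop=cop, emg=emg)
    fit = fit_muscle_model(table)
    assert fit.beta[0] < 0 and fit.beta[1] > 0 and fit.beta[2] > 0
    ref = np.linalg.solve(table.emg.T @ table.emg, table.emg.T @ table.cop_shift)
    np.testing.assert_allclose(fit.beta, ref, atol=1e-10)
    # degenerate design: all scalars zero
    table.emg = np.zeros_like(table.emg)
    with pytest.raises((CollinearityError, InsufficientDataError)):
        fit_muscle_model(table)


# ------------------------------------------------------------------ AEV ----

def test_aev_identity_and_equivariance(rng):
    table, e = _make_table(rng)
    table.cop_shift = -0.3 * (e - e.mean()) + 0.005 * rng.standard_normal(len(table))
    table.cop_shift -= table.cop_shift.mean()
    fit1 = _fit1_from(table)
    fit2 = fit_ankle_strategy_model(table, fit1, 25)
    sd_pop = np.sqrt(np.mean(table.cop_shift**2))
    assert fit2.aev == pytest.approx(np.sqrt(fit2.r2) * sd_pop * 100, abs=1e-10)
    # perfect fit: AEV equals the population SD of the outcome
    aev = absolute_explained_variance(table.cop_shift)
    assert aev == pytest.approx(sd_pop * 100, abs=1e-12)
    assert absolute_explained_variance(np.zeros(10)) == 0.0
    # scale equivariance: y * k scales beta and AEV by k, leaves r2 alone
    table.cop_shift *= 3.0
    fit2k = fit_ankle_strategy_model(table, fit1, 25)
    assert fit2k.beta_error == pytest.approx(3 * fit2.beta_error, rel=1e-9)
    assert fit2k.aev == pytest.approx(3 * fit2.aev, rel=1e-9)
    assert fit2k.r2 == pytest.approx(fit2.r2, rel=1e-9)
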