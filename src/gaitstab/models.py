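"""The three chained regressions of the stability analysis.

Model 1 (foot placement): demeaned ML foot placement on the demeaned
CoM-state predictors, one two-predictor fit per normalized swing sample
``i = 1..51``. Its residuals are the foot-placement errors (positive = too
lateral).

Model 2 (ankle strategy): demeaned single-stance CoP shift on the
foot-placement error at mid-swing (i=25) or terminal swing (i=51); the
expected coefficient is negative (stepping too medial is compensated by a
lateral CoP shift and vice versa).

Model 3 (muscle model): the same CoP shift on the three demeaned early-stance
EMG scalars; peroneus longus is expected negative (eversion shifts the CoP
medially), tibialis anterior and soleus positive.

Everything is demeaned upstream, so no regression carries an intercept and
R^2 is computed about zero. The absolute explained variance (AEV) is the
root of the step-averaged squared fitted value, reported in cm: the
magnitude of the average explained CoP shift. Algebraically
AEV = sqrt(R^2) * population SD of the dependent variable.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .config import HEELSTRIKE_INDEX, MIDSWING_INDEX, SWING_SAMPLES
from .exceptions import CollinearityError, InsufficientDataError
from .kinematics import StepTable

_M_TO_CM = 100.0


@dataclass
class FootPlacementFit:
    beta_pos: np.ndarray      # (51,) gain per CoM-position unit at each index
    beta_vel: np.ndarray      # (51,)
    r2: np.ndarray            # (51,) relative explained variance
    error_fp: np.ndarray      # (n, 51) residuals (m); positive = too lateral
    fitted: np.ndarray        # (n, 51)


@dataclass
class AnkleStrategyFit:
    i_used: int               # 1-based swing index: 25 (mid-swing) or 51
    subset: str               # {all, medial_only, lateral_only}
    beta_error: float         # dimensionless
    r2: float
    aev: float                # cm
    residuals: np.ndarray     # (n,) m
    fitted: np.ndarray        # (n,) m
    n_steps: int = 0


@dataclass
class MuscleFit:
    beta: np.ndarray          # (3,) m per EMG-scalar unit (PL, TA, SO)
    r2: float
    aev: float                # cm
    residuals: np.ndarray
    fitted: np.ndarray
    n_steps: int = 0

    @property
    def beta_cm(self) -> np.ndarray:
        return self.beta * _M_TO_CM


def ols_no_intercept(y: np.ndarray, X: np.ndarray):
    """Least squares without intercept; R^2 about zero (variables demeaned).

    Returns ``(coef, residuals, fitted, r2)``. Raises on rank deficiency or
    when there are no more rows than columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and y.size > 1:
        X = X.T
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    if n <= p:
        raise InsufficientDataError(f"{n} rows cannot identify {p} coefficients")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise CollinearityError("design matrix is rank deficient")
    fitted = X @ coef
    resid = y - fitted
    ss_tot = float(y @ y)
    if ss_tot == 0.0:
        raise InsufficientDataError("dependent variable has zero variance")
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return coef, resid, fitted, r2


def fit_foot_placement_model(table: StepTable) -> FootPlacementFit:
    """Model 1: one 2-predictor fit per normalized swing sample index."""
    n = len(table)
    if n < 10:
        raise InsufficientDataError(f"only {n} steps; need at least 10")
    beta_pos = np.empty(SWING_SAMPLES)
    beta_vel = np.empty(SWING_SAMPLES)
    r2 = np.empty(SWING_SAMPLES)
    error_fp = np.empty((n, SWING_SAMPLES))
    fitted = np.empty((n, SWING_SAMPLES))
    for i in range(SWING_SAMPLES):
        X = np.column_stack([table.com_pos[:, i], table.com_vel[:, i]])
        coef, resid, fit_i, r2_i = ols_no_intercept(table.fp, X)
        beta_pos[i], beta_vel[i] = coef
        r2[i] = r2_i
        error_fp[:, i] = resid
        fitted[:, i] = fit_i
    return FootPlacementFit(beta_pos=beta_pos, beta_vel=beta_vel, r2=r2,
                            error_fp=error_fp, fitted=fitted)


def fit_ankle_strategy_model(
    table: StepTable,
    fit1: FootPlacementFit,
    i_used: int = MIDSWING_INDEX,
    subset: str = "all",
) -> AnkleStrategyFit:
    """Model 2: CoP shift on the foot-placement error at ``i_used``.

    ``subset='medial_only'`` keeps steps with negative error (too medial),
    ``'lateral_only'`` the positive ones; subsets are re-demeaned before the
    fit so the no-intercept regression stays centered.
    """
    if i_used not in (MIDSWING_INDEX, HEELSTRIKE_INDEX):
        raise ValueError(f"i_used must be {MIDSWING_INDEX} or {HEELSTRIKE_INDEX}")
    err = fit1.error_fp[:, i_used - 1]
    y = table.cop_shift
    if subset == "medial_only":
        keep = err < 0
    elif subset == "lateral_only":
        keep = err > 0
    elif subset == "all":
        keep = np.ones(len(err), dtype=bool)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    err, y = err[keep], y[keep]
    if err.size < 10:
        raise InsufficientDataError(
            f"subset {subset!r} leaves only {err.size} steps (need 10)"
        )
    if subset != "all":
        err = err - err.mean()
        y = y - y.mean()
    coef, resid, fitted, r2 = ols_no_intercept(y, err[:, None])
    return AnkleStrategyFit(
        i_used=i_used, subset=subset, beta_error=float(coef[0]), r2=r2,
        aev=absolute_explained_variance(fitted), residuals=resid,
        fitted=fitted, n_steps=int(err.size),
    )


def fit_muscle_model(table: StepTable) -> MuscleFit:
    """Model 3: CoP shift on the three early-stance EMG scalars."""
    if table.emg is None:
        raise InsufficientDataError("step table carries no EMG scalars")
    if len(table) < 10:
        raise InsufficientDataError(f"only {len(table)} steps; need at least 10")
    coef, resid, fitted, r2 = ols_no_intercept(table.cop_shift, table.emg)
    return MuscleFit(beta=coef, r2=r2, aev=absolute_explained_variance(fitted),
                     residuals=resid, fitted=fitted, n_steps=len(table))


def absolute_explained_variance(fitted: np.ndarray) -> float:
    """AEV in cm: root of the step-averaged squared fitted (demeaned) CoP shift.

    Identical to sqrt(R^2) times the population SD of the dependent variable.
    """
    fitted = np.asarray(fitted, dtype=float)
    if fitted.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(fitted ** 2))) * _M_TO_CM
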