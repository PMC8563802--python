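"""CoM estimation, foot frames, CoP shifts, predictor assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitstab import (
    RunConfig,
    SynthParams,
    analyze_trial,
    build_foot_frame,
    compute_com,
    compute_cop_shift,
    cop_to_local,
    generate_trial,
)
from gaitstab.exceptions import DegenerateGeometryError, InsufficientDataError
from gaitstab.kinematics import resample_step

# axis-aligned RIGHT foot pointing +X with +Y to the subject's left:
# the medial malleolus sits on the +Y (inner) side
CANONICAL = dict(
    medial_malleolus=np.array([0.0, 0.04, 0.07]),
    lateral_malleolus=np.array([0.0, -0.04, 0.07]),
    calcaneus=np.array([-0.05, 0.0, 0.0]),
    toe=np.array([0.20, 0.0, 0.0]),
)


# ---------------------------------------------------------------- CoM ------

def test_single_segment_com_is_its_midpoint():
    t = np.arange(0, 1, 0.02)
    prox = np.column_stack([t * 0, t * 0 + 0.2, t * 0 + 1.0])
    dist = np.column_stack([t * 0, t * 0 + 0.2, t * 0])
    anthro = pd.DataFrame({"segment": ["trunk"], "mass_fraction": [1.0],
                           "com_fraction": [0.5]})
    com = compute_com({"trunk": (prox, dist)}, anthro, t)
    np.testing.assert_allclose(com.pos, 0.2)


def test_two_equal_masses_average():
    t = np.arange(0, 1, 0.02)
    mk = lambda y: (np.column_stack([t * 0, t * 0 + y, t * 0 + 1]),
                    np.column_stack([t * 0, t * 0 + y, t * 0]))
    anthro = pd.DataFrame({"segment": ["a", "b"], "mass_fraction": [0.5, 0.5],
                           "com_fraction": [0.5, 0.5]})
    com = compute_com({"a": mk(0.0), "b": mk(1.0)}, anthro, t)
    np.testing.assert_allclose(com.pos, 0.5)


def test_com_velocity_matches_analytic_derivative():
    t = np.arange(0, 2, 0.02)
    pos = np.sin(2 * np.pi * t)
    seg = (np.column_stack([t * 0, pos, t * 0 + 1]),
           np.column_stack([t * 0, pos, t * 0]))
    anthro = pd.DataFrame({"segment": ["a"], "mass_fraction": [1.0],
                           "com_fraction": [0.5]})
    com = compute_com({"a": seg}, anthro, t)
    bound = (2 * np.pi) ** 3 / (6 * 50**2)
    interior = slice(1, -1)
    err = np.abs(com.vel[interior] - 2 * np.pi * np.cos(2 * np.pi * t[interior]))
    assert err.max() <= bound


def test_missing_segment_and_zero_mass_errors():
    t = np.arange(0, 1, 0.02)
    anthro = pd.DataFrame({"segment": ["pelvis"], "mass_fraction": [1.0],
                           "com_fraction": [0.5]})
    with pytest.raises(KeyError, match="pelvis"):
        compute_com({}, anthro, t)
    anthro0 = anthro.assign(mass_fraction=[0.0])
    with pytest.raises(ValueError):
        compute_com({"pelvis": (np.zeros((len(t), 3)), np.zeros((len(t), 3)))},
                    anthro0, t)


# ---------------------------------------------------------------- frames ---

def test_canonical_right_foot_frame():
    f = build_foot_frame(side="right", **CANONICAL)
    # lateral is -Y for the right foot; forward flips with it (handedness)
    np.testing.assert_allclose(f.axes[1], [0.0, -1.0, 0.0], atol=1e-12)
    assert f.axes[2] @ [0, 0, 1] > 0.99  # vertical points up
    np.testing.assert_allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-12)
    assert np.linalg.det(f.axes) == pytest.approx(1.0)


def test_frame_rotation_equivariance(rng):
    f0 = build_foot_frame(side="left", **CANONICAL)
    for _ in range(25):
        rot = stats.special_ortho_group.rvs(3, random_state=rng)
        pts = {k: rot @ v for k, v in CANONICAL.items()}
        f = build_foot_frame(side="left", **pts)
        np.testing.assert_allclose(f.axes, f0.axes @ rot.T, atol=1e-10)


def test_collinear_landmarks_rejected():
    line = {k: np.array([i * 0.1, 0.0, 0.0]) for i, k in
            enumerate(["medial_malleolus", "lateral_malleolus", "calcaneus", "toe"])}
    with pytest.raises(DegenerateGeometryError):
        build_foot_frame(side="left", **line)


def test_cop_local_sign_convention_and_roundtrip(rng):
    f = build_foot_frame(side="right", **CANONICAL)
    assert cop_to_local(f.origin, f)[0] == pytest.approx(0.0)
    # +0.02 m along the frame's lateral direction reads +0.02 (Fig-style check)
    shifted = f.origin + 0.02 * f.lateral_axis
    assert cop_to_local(shifted, f)[0] == pytest.approx(0.02)
    for _ in range(50):
        rot = stats.special_ortho_group.rvs(3, random_state=rng)
        pts = {k: rot @ v + rng.standard_normal(3) for k, v in CANONICAL.items()}
        fr = build_foot_frame(side="right", **pts)
        local = rng.standard_normal((8, 3)) * 0.05
        np.testing.assert_allclose(fr.to_local(fr.to_global(local)), local,
                                   atol=1e-10)


# ------------------------------------------------------------- CoP shift ---

def test_cop_shift_constant_and_ramp():
    t = np.arange(0, 1, 0.001)
    assert compute_cop_shift(np.full(t.size, 0.3), t, (0.2, 0.8)) == pytest.approx(0.0)
    ramp = np.interp(t, [0.2, 0.8], [0.0, 0.01])
    # mean of a linear 0 -> 1 cm ramp is +0.5 cm
    assert compute_cop_shift(ramp, t, (0.2, 0.8)) == pytest.approx(0.005, abs=1e-5)
    with pytest.raises(InsufficientDataError):
        compute_cop_shift(ramp, t, (0.5, 0.5))


def test_injected_cop_shifts_recovered(small_trial, small_result):
    """Generator truth oracle: per-step shifts recovered at 1000 Hz precision."""
    truth = small_trial.truth.steps.set_index(["side", "t_heelstrike"])
    table = small_result.step_table
    wdf = small_result.windows.table
    measured = table.cop_shift + table.cop_shift_mean
    for j, row in enumerate(wdf.itertuples(index=False)):
        want = truth.loc[(row.side, round(row.heel_strike_t, 6))]["cop_shift"]
        assert measured[j] == pytest.approx(want, abs=1e-9)


# ------------------------------------------------------------ predictors ---

def test_step_table_demeaning_contract(small_result):
    table = small_result.step_table
    assert abs(table.fp.mean()) < 1e-12
    assert abs(table.cop_shift.mean()) < 1e-12
    assert np.abs(table.com_pos.mean(axis=0)).max() < 1e-12
    assert np.abs(table.com_vel.mean(axis=0)).max() < 1e-12
    assert np.abs(table.emg.mean(axis=0)).max() < 1e-12
    assert table.com_pos.shape[1] == 51 and table.com_vel.shape[1] == 51


def test_symmetric_constant_gait_has_zero_demeaned_fp():
    """Constant step width: every demeaned foot placement vanishes.

    Model fitting is skipped here — with no step-to-step CoM offset the two
    predictors are deliberately collinear.
    """
    from gaitstab import RunConfig, detect_gait_events, segment_strides
    from gaitstab.io import bundle_from_trial
    from gaitstab.pipeline import build_step_table

    p = SynthParams(n_strides=12, seed=5, sigma_fp=0.0, sigma_com_offset=0.0,
                    ar1_rho=0.0, synthesize_emg=False)
    trial = generate_trial(p)
    bundle = bundle_from_trial(trial)
    ev = detect_gait_events(trial.force_t,
                            {s: trial.forces[s]["fz"] for s in trial.forces},
                            trial.body_weight)
    windows = segment_strides(ev, select_n=12)
    table = build_step_table(bundle, windows, RunConfig(select_n_strides=12))
    assert np.abs(table.fp).max() < 1e-9


def test_resampling_matches_bruteforce_oracle(rng):
    t = np.arange(0, 3, 0.02)
    series = rng.standard_normal(t.size).cumsum()
    t0, t1 = 0.513, 1.207
    mine = resample_step(t, series, t0, t1)
    # independent brute-force linear interpolation
    want = np.empty(51)
    for i in range(51):
        ti = t0 + (t1 - t0) * i / 50
        k = np.searchsorted(t, ti) - 1
        w = (ti - t[k]) / (t[k + 1] - t[k])
        want[i] = series[k] * (1 - w) + series[k + 1] * w
    np.testing.assert_allclose(mine, want, atol=1e-9)
    # endpoints preserved exactly when they fall on samples
    grid = resample_step(t, series, t[10], t[40])
    assert grid[0] == series[10] and grid[-1] == series[40]
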