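"""Self-validation routines: generative recovery, sign structure, oracles.

These functions re-run the full pipeline on freshly generated synthetic
cohorts and measure how well it recovers the injected ground truth. They are
the computational backbone of both the acceptance test suite and
``scripts/acceptance.py``; every quantity is recomputed from scratch at call
time, seeded explicitly.

Problem sizes default to the study's conditions (30 participants, 200
strides) where a check estimates a per-trial quantity, and to 50-stride
trials for the Bayesian sign-structure cohorts, where group-level
t-statistics are far above threshold and the shorter trials keep the
full-EMG synthesis affordable.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import bf_from_t, bf_one_sample_jzs, bf_one_sample_monte_carlo, bf_rm_anova_2x2
from .config import RunConfig, SPEED_COEFFICIENTS, RSCALE_DEFAULT, walking_speed
from .events import detect_gait_events
from .kinematics import build_foot_frame, cop_to_local
from .models import absolute_explained_variance, ols_no_intercept
from .pipeline import analyze_trial
from .synth import SynthParams, cohort_params, generate_trial

_STEADY_NORMAL = [("steady", "normal")]


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Child integer seeds below 2**31 derived from one root seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


# ---------------------------------------------------------------------------
# generative parameter recovery
# ---------------------------------------------------------------------------

def parameter_recovery(
    seed: int,
    n_cohort_seeds: int = 100,
    n_participants: int = 30,
    n_strides: int = 200,
    base_params: SynthParams | None = None,
) -> Dict[str, dict]:
    """Bias check: recovered model-1/2 coefficients vs injected truth.

    Streams ``n_cohort_seeds`` cohorts of ``n_participants`` (steady-state,
    normal speed, realistic noise, no raw EMG — the CoP-shift muscle
    component is injected from the latent scalars either way) and pools the
    per-trial recovery errors. For each coefficient returns the mean error,
    its Monte-Carlo SE, and the z ratio; an unbiased pipeline keeps |z| <~ 2.
    """
    if base_params is None:
        base_params = SynthParams(synthesize_emg=False)
    base_params = replace(base_params, n_strides=n_strides, synthesize_emg=False)
    config = RunConfig(select_n_strides=n_strides)
    errors = {"beta_pos": [], "beta_vel": [], "beta_error": []}
    for s in _spawn_seeds(seed, n_cohort_seeds):
        cells = cohort_params(n_participants, _STEADY_NORMAL, base_params, int(s))
        for params in cells.values():
            trial = generate_trial(params)
            res = analyze_trial(trial, config)
            truth = trial.truth.coefficients
            i = 25 - 1
            errors["beta_pos"].append(res.fit1.beta_pos[i] - truth["beta_pos"])
            errors["beta_vel"].append(res.fit1.beta_vel[i] - truth["beta_vel"])
            errors["beta_error"].append(res.fit2[25].beta_error - truth["beta_error"])
    out = {}
    for name, errs in errors.items():
        errs = np.asarray(errs)
        se = errs.std(ddof=1) / math.sqrt(errs.size)
        out[name] = {
            "mean_error": float(errs.mean()),
            "mc_se": float(se),
            "z": float(errs.mean() / se) if se > 0 else 0.0,
            "n": int(errs.size),
        }
    return out


# ---------------------------------------------------------------------------
# Bayesian sign structure
# ---------------------------------------------------------------------------

_COEFS = ("beta_error_25", "beta_pl", "beta_ta", "beta_so")


def sign_structure(
    seed: int,
    n_cohort_seeds: int = 20,
    n_participants: int = 30,
    n_strides: int = 50,
    null: bool = False,
    rscale: float = RSCALE_DEFAULT,
) -> dict:
    """Group-level JZS Bayes factors for the four coupling coefficients.

    With the directed couplings (beta_error < 0; PL < 0, TA > 0, SO > 0) a
    healthy pipeline yields BF10 > 10 for every coefficient in nearly every
    cohort seed; under a null generator (all CoP couplings zero) the median
    BF10 favors the null.
    """
    base = SynthParams(n_strides=n_strides)
    if null:
        base = replace(base, beta_error=0.0, muscle_gains=(0.0, 0.0, 0.0))
    config = RunConfig(select_n_strides=n_strides)
    per_seed = []
    for s in _spawn_seeds(seed, n_cohort_seeds):
        cells = cohort_params(n_participants, _STEADY_NORMAL, base, int(s))
        rows = []
        for (pid, cond, speed), params in cells.items():
            res = analyze_trial(generate_trial(params), config,
                                participant=pid, condition=cond, speed=speed)
            rows.append(res.summary)
        fit_table = pd.DataFrame(rows)
        bfs = {}
        for coef in _COEFS:
            vals = fit_table[coef].to_numpy()
            bfs[coef] = bf_one_sample_jzs(vals, rscale=rscale).bf10
        signs_ok = (
            fit_table["beta_error_25"].mean() < 0
            and fit_table["beta_pl"].mean() < 0
            and fit_table["beta_ta"].mean() > 0
            and fit_table["beta_so"].mean() > 0
        )
        per_seed.append({"bf10": bfs, "signs_ok": bool(signs_ok)})
    all_above = [all(r["bf10"][c] > 10.0 for c in _COEFS) for r in per_seed]
    medians = {c: float(np.median([r["bf10"][c] for r in per_seed])) for c in _COEFS}
    return {
        "per_seed": per_seed,
        "fraction_all_bf_above_10": float(np.mean(all_above)),
        "fraction_signs_correct": float(np.mean([r["signs_ok"] for r in per_seed])),
        "median_bf10_per_coef": medians,
        "max_median_bf10": float(max(medians.values())),
    }


# ---------------------------------------------------------------------------
# ankle-constraint effect direction
# ---------------------------------------------------------------------------

def constraint_effect(
    seed: int,
    n_participants: int = 30,
    n_strides: int = 50,
) -> dict:
    """Ankle-moment constraint lowers model-2 AEV; Condition enters the 2x2.

    Runs a cohort over the (steady, ankle_constrained) x (normal, slow)
    design and measures (a) the fraction of participant-by-speed pairs whose
    AEV drops under the constraint and (b) whether the Bayesian 2x2
    comparison prefers a model containing Condition.
    """
    design = [(c, sp) for c in ("steady", "ankle_constrained")
              for sp in ("normal", "slow")]
    base = SynthParams(n_strides=n_strides, synthesize_emg=False)
    config = RunConfig(select_n_strides=n_strides)
    rows = []
    for (pid, cond, speed), params in cohort_params(
            n_participants, design, base, seed).items():
        res = analyze_trial(generate_trial(params), config,
                            participant=pid, condition=cond, speed=speed)
        rows.append(res.summary)
    fit_table = pd.DataFrame(rows)
    wide = fit_table.pivot_table(index=["participant", "speed"],
                                 columns="condition", values="aev2_25")
    lower = wide["ankle_constrained"] < wide["steady"]
    anova = bf_rm_anova_2x2(
        fit_table[["participant", "condition", "speed", "aev2_25"]],
        value_col="aev2_25")
    condition_in_best = ("condition" in anova.best_model
                         or "interaction" in anova.best_model)
    return {
        "fraction_participants_lower_aev": float(lower.mean()),
        "best_model": anova.best_model,
        "condition_in_best_model": bool(condition_in_best),
        "anova_bf10": anova.bf10,
        "n": int(len(wide)),
    }


# ---------------------------------------------------------------------------
# calibration plausibility
# ---------------------------------------------------------------------------

def calibration_r2(
    seed: int,
    n_participants: int = 30,
    n_strides: int = 200,
) -> dict:
    """Median trial-level ankle-strategy R^2 of the default synthetic cohort."""
    base = SynthParams(n_strides=n_strides, synthesize_emg=False)
    config = RunConfig(select_n_strides=n_strides)
    r2 = []
    for params in cohort_params(n_participants, _STEADY_NORMAL, base, seed).values():
        res = analyze_trial(generate_trial(params), config)
        r2.append(res.fit2[25].r2)
    return {"median_r2": float(np.median(r2)), "r2": r2, "n": len(r2)}


# ---------------------------------------------------------------------------
# numeric oracle equivalences
# ---------------------------------------------------------------------------

def oracle_equivalences(seed: int, mc_draws: int = 1_000_000) -> dict:
    """Dual-route numeric checks.

    * OLS vs explicit normal equations on random designs,
    * JZS quadrature vs Monte-Carlo prior integration on an (n, t) grid,
    * the AEV identity AEV = sqrt(R^2) * population SD of the outcome.
    """
    rng = np.random.default_rng(seed)
    ols_dev = 0.0
    aev_dev = 0.0
    for _ in range(20):
        n, p = int(rng.integers(20, 200)), int(rng.integers(1, 5))
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        coef, _, fitted, r2 = ols_no_intercept(y, X)
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        ols_dev = max(ols_dev, float(np.max(np.abs(coef - ref))
                                     / max(np.max(np.abs(ref)), 1e-12)))
        aev = absolute_explained_variance(fitted)
        ident = math.sqrt(max(r2, 0.0)) * float(np.sqrt(np.mean(y**2))) * 100.0
        aev_dev = max(aev_dev, abs(aev - ident))
    jzs_dev = 0.0
    mc_seeds = _spawn_seeds(seed, 1)
    for n in (5, 15, 30, 60):
        for t in (0.0, 1.0, 2.0, 4.0, 8.0):
            quad = bf_from_t(t, n).bf10
            mc = bf_one_sample_monte_carlo(t, n, n_draws=mc_draws,
                                           seed=int(mc_seeds[0]))
            jzs_dev = max(jzs_dev, abs(quad - mc) / mc)
    return {
        "ols_max_rel_dev": ols_dev,
        "aev_identity_max_dev": aev_dev,
        "jzs_quad_vs_mc_max_rel_dev": jzs_dev,
    }


# ---------------------------------------------------------------------------
# event detection and frame geometry
# ---------------------------------------------------------------------------

def event_detection_accuracy(
    seed: int,
    n_seeds: int = 50,
    n_strides: int = 20,
) -> dict:
    """Detected vs injected event times over many random trials (both ways)."""
    worst = 0.0
    n_events = 0
    for s in _spawn_seeds(seed, n_seeds):
        trial = generate_trial(SynthParams(n_strides=n_strides, seed=int(s),
                                           synthesize_emg=False))
        ev = detect_gait_events(
            trial.force_t, {k: v["fz"] for k, v in trial.forces.items()},
            trial.body_weight)
        for side in ("left", "right"):
            for det, tru in ((ev.heel_strikes[side], trial.truth.heel_strikes[side]),
                             (ev.toe_offs[side], trial.truth.toe_offs[side])):
                if len(tru) == 0 or len(det) == 0:
                    worst = math.inf
                    continue
                for t in tru:
                    worst = max(worst, float(np.min(np.abs(det - t))))
                for t in det:
                    worst = max(worst, float(np.min(np.abs(tru - t))))
                n_events += len(tru)
    return {"max_abs_dt_ms": worst * 1000.0, "n_events": n_events}


def frame_geometry_checks(seed: int, n_poses: int = 1000) -> dict:
    """Foot-frame orthonormality, rotation equivariance, CoP round trips."""
    rng = np.random.default_rng(seed)
    base_pts = {
        "med": np.array([0.0, -0.04, 0.07]),
        "lat": np.array([0.0, 0.04, 0.07]),
        "cal": np.array([-0.05, 0.0, 0.0]),
        "toe": np.array([0.20, 0.0, 0.0]),
    }
    ortho_dev = 0.0
    equiv_dev = 0.0
    round_dev = 0.0
    frame0 = build_foot_frame(base_pts["med"], base_pts["lat"],
                              base_pts["cal"], base_pts["toe"], "right")
    for _ in range(n_poses):
        rot = stats.special_ortho_group.rvs(3, random_state=rng)
        shift = rng.standard_normal(3)
        pts = {k: rot @ v + shift for k, v in base_pts.items()}
        frame = build_foot_frame(pts["med"], pts["lat"], pts["cal"], pts["toe"],
                                 "right")
        ortho_dev = max(ortho_dev, float(np.max(np.abs(
            frame.axes @ frame.axes.T - np.eye(3)))))
        equiv_dev = max(equiv_dev, float(np.max(np.abs(
            frame.axes - frame0.axes @ rot.T))))
        local = rng.standard_normal((5, 3)) * 0.05
        back = frame.to_local(frame.to_global(local))
        round_dev = max(round_dev, float(np.max(np.abs(back - local))))
        ml = cop_to_local(frame.to_global(local), frame)
        round_dev = max(round_dev, float(np.max(np.abs(ml - local[:, 1]))))
    return {
        "orthonormality_max_dev": ortho_dev,
        "rotation_equivariance_max_dev": equiv_dev,
        "cop_roundtrip_max_dev": round_dev,
    }


# ---------------------------------------------------------------------------
# pinned protocol constants
# ---------------------------------------------------------------------------

def protocol_constants() -> dict:
    """The protocol's pinned constants as the configuration reproduces them."""
    from . import config as c

    return {
        "speed_coefficient_normal": SPEED_COEFFICIENTS["normal"],
        "speed_coefficient_slow": SPEED_COEFFICIENTS["slow"],
        "speed_normal_leg1m": walking_speed(1.0, "normal"),
        "strides_analyzed": c.N_STRIDES_DEFAULT,
        "swing_samples": c.SWING_SAMPLES,
        "midswing_index": c.MIDSWING_INDEX,
        "heelstrike_index": c.HEELSTRIKE_INDEX,
        "stride_emg_samples": c.STRIDE_EMG_SAMPLES,
        "early_stance_fraction": c.EARLY_STANCE_FRACTION,
        "emg_highpass_hz": c.EMG_HIGHPASS_HZ,
        "emg_lowpass_hz": c.EMG_LOWPASS_HZ,
        "kinematic_rate": c.KINEMATIC_RATE,
        "force_rate": c.FORCE_RATE,
        "emg_rate": c.EMG_RATE,
        "rscale_default": c.RSCALE_DEFAULT,
    }
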