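"""Synthetic gait trials with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* mediolateral foot placement linearly coupled to the swing-phase CoM state
  (position and velocity relative to the stance foot),
* a negative coupling from the foot-placement error to the subsequent
  single-stance CoP shift under the placed foot (the "ankle strategy"),
* signed muscle gains linking early-stance EMG scalars (peroneus longus
  negative; tibialis anterior and soleus positive) to the same CoP shift,
* two walking speeds and three conditions (steady state, ankle-moment
  constrained with suppressed CoP-shift gain/variance, foot-placement
  constrained with suppressed foot-placement variance).

It is *not* a forward-dynamic simulation: trajectories are kinematic
stand-ins shaped so that every quantity the downstream pipeline measures
(events from per-belt forces, foot placement at mid-stance, 51-sample
CoM-state predictors, single-stance CoP shifts, early-stance EMG scalars)
equals the injected ground truth, exactly where the coupling identities are
concerned and within discretization noise elsewhere.

The per-step CoM-state variability is realized as a constant offset plus a
geometrically decaying mode whose decay rate is tied to the generating gains
(``z`` solves ``z - 1/z = -2*dt*beta_pos/beta_vel``). That choice makes the
foot-placement regression identity hold exactly under the pipeline's
central-difference velocity and linear resampling operators, so noise-free
trials are recovered to machine precision end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    EMG_RATE,
    FORCE_RATE,
    KINEMATIC_RATE,
    MUSCLES,
    SIDES,
    walking_speed,
)
from .exceptions import ConfigurationError

_KIN_DT = 1.0 / KINEMATIC_RATE          # 20 ms
_STRIDE_GRID_MS = 40                    # stride time snapped to this grid
_EDGE_MARGIN = 2                        # kinematic samples of structured margin
_RECT_MEAN = math.sqrt(2.0 / math.pi)   # E|N(0,1)|: rectified-carrier scale

GRAVITY = 9.81


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration for one trial.

    Couplings and noise magnitudes default to values that place the
    ankle-strategy regression's per-trial R^2 near 0.1 with demeaned
    foot-placement SD near 1 cm; ``beta_error`` and the muscle gains carry
    the physiologically expected signs.
    """

    n_strides: int = 200
    stride_time: float = 1.12            # s; snapped to the 40 ms grid
    leg_length: float = 0.9              # m
    body_mass: float = 70.0              # kg
    speed: str = "normal"                # {normal, slow}
    condition: str = "steady"            # {steady, ankle_constrained, fp_constrained}
    beta_pos: float = 0.5                # FP per CoM-position unit
    beta_vel: float = 0.2                # FP per CoM-velocity unit (s); must be != 0
    beta_error: float = -0.3             # CoP shift per FP error (dimensionless)
    muscle_gains: Tuple[float, float, float] = (-0.5, 0.3, 0.3)  # cm per scalar (PL, TA, SO)
    sigma_fp: float = 0.007              # FP error SD (m)
    sigma_cop: float = 0.006             # non-muscle CoP-shift noise SD (m)
    sigma_emg: float = 0.5               # fractional EMG burst-amplitude SD
    sigma_com_offset: float = 0.015      # per-step CoM offset SD (m)
    sigma_com_mode: float = 0.008        # per-step decaying-mode amplitude SD (m)
    ar1_rho: float = 0.3                 # step-to-step AR(1) of the CoM offset
    step_width_mean: float = 0.10        # m
    double_support_fraction: float = 0.2 # of the stride
    ankle_constraint_scale: float = 0.2  # applied to beta_error, gains, sigma_cop
    fp_constraint_scale: float = 0.2     # applied to sigma_fp, sigma_com_offset
    emg_base_level: Tuple[float, float, float] = (2.3, 1.8, 2.8)  # device units
    synthesize_emg: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_strides < 3:
            raise ConfigurationError(
                "n_strides must be >= 3 to form a complete step chain"
            )
        if self.stride_time <= 0:
            raise ConfigurationError("stride_time must be positive")
        for name in ("sigma_fp", "sigma_cop", "sigma_emg",
                     "sigma_com_offset", "sigma_com_mode"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.beta_vel == 0:
            raise ConfigurationError(
                "beta_vel must be non-zero (the CoM-velocity coupling sets the "
                "decay rate of the per-step CoM mode)"
            )
        if self.speed not in ("normal", "slow"):
            raise ConfigurationError(f"unknown speed {self.speed!r}")
        if self.condition not in ("steady", "ankle_constrained", "fp_constrained"):
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if not (0 < self.double_support_fraction < 0.5):
            raise ConfigurationError("double_support_fraction must be in (0, 0.5)")
        if self.leg_length <= 0 or self.body_mass <= 0:
            raise ConfigurationError("leg_length and body_mass must be positive")


@dataclass
class TruthLog:
    """Ground truth injected into a trial."""

    heel_strikes: Dict[str, np.ndarray]
    toe_offs: Dict[str, np.ndarray]
    steps: pd.DataFrame            # one row per step with injected quantities
    coefficients: Dict[str, object]


@dataclass
class SynthTrial:
    """A complete simulated trial on native clocks."""

    params: SynthParams
    kin_t: np.ndarray                                  # 50 samples/s
    landmarks: Dict[str, np.ndarray]                   # name -> (N, 3)
    segments: Dict[str, Tuple[np.ndarray, np.ndarray]] # name -> (prox, dist)
    force_t: np.ndarray                                # 1000 samples/s
    forces: Dict[str, Dict[str, np.ndarray]]           # side -> {fz, cop}
    emg_t: np.ndarray | None                           # 2000 samples/s
    emg: Dict[Tuple[str, str], np.ndarray] | None      # (side, muscle) -> raw
    truth: TruthLog
    body_weight: float                                 # N


def snap_stride_time_ms(stride_time: float) -> int:
    """Stride time in ms, snapped to the 40 ms grid.

    The snap keeps every heel strike on the force-plate clock and keeps the
    left- and right-step resampling grids phase-aligned on the kinematic
    clock, which is what lets the shared mean swing profile cancel exactly
    under per-sample demeaning.
    """
    t_ms = int(round(stride_time * 1000.0 / _STRIDE_GRID_MS)) * _STRIDE_GRID_MS
    return max(t_ms, _STRIDE_GRID_MS)


def _mirror_sign(side: str) -> float:
    # lateral-positive convention: +Y is lateral for the left foot,
    # -Y is lateral for the right foot (global Y points to the subject's left)
    return 1.0 if side == "left" else -1.0


def _effective(params: SynthParams):
    """Condition scalings applied to the generating parameters."""
    beta_error = params.beta_error
    gains = np.asarray(params.muscle_gains, dtype=float)
    sigma_cop = params.sigma_cop
    sigma_fp = params.sigma_fp
    sigma_p = params.sigma_com_offset
    if params.condition == "ankle_constrained":
        s = params.ankle_constraint_scale
        beta_error *= s
        gains = gains * s
        sigma_cop *= s
    elif params.condition == "fp_constrained":
        s = params.fp_constraint_scale
        sigma_fp *= s
        sigma_p *= s
    return beta_error, gains, sigma_cop, sigma_fp, sigma_p


def _mean_swing_profile(tau: np.ndarray, step_width: float) -> np.ndarray:
    """Mean CoM trajectory relative to the stance foot (lateral positive)."""
    return 0.5 * step_width - 0.012 * np.sin(np.pi * np.clip(tau, -0.2, 1.2))


def generate_trial(params: SynthParams) -> SynthTrial:
    """Generate one synthetic trial. Deterministic under ``params.seed``."""
    params.validate()
    t_ms = snap_stride_time_ms(params.stride_time)
    stance_ms = int(round(t_ms * (0.5 + params.double_support_fraction / 2.0)))
    half_ms = t_ms // 2
    d1_ms = stance_ms - half_ms          # double-support duration after HS
    if d1_ms < 100:
        raise ConfigurationError(
            "double-support phase shorter than 100 ms: increase stride_time or "
            "double_support_fraction (the structured CoM construction needs a "
            "two-sample margin around each swing window)"
        )
    n = params.n_strides
    t0_ms = t_ms                          # first fully-formed right heel strike
    dur_ms = t0_ms + n * t_ms + half_ms + stance_ms + t_ms

    rng = np.random.default_rng(params.seed)
    beta_error, gains_cm, sigma_cop, sigma_fp, sigma_p = _effective(params)
    gains_m = gains_cm / 100.0
    speed_mps = walking_speed(params.leg_length, params.speed)
    stride_s = t_ms / 1000.0

    # ---- event schedule (ms, exact) -------------------------------------
    # right heel strikes at t0 + k*T, left heel strikes offset by T/2
    hs_ms = {
        "right": np.array([t0_ms + k * t_ms for k in range(-1, n + 1)]),
        "left": np.array([t0_ms + k * t_ms + half_ms for k in range(-2, n + 1)]),
    }
    to_ms = {s: hs_ms[s] + stance_ms for s in SIDES}

    # chronological steps: swing (TO, HS]; each entry consumes hs index k+1
    steps: List[dict] = []
    for side in SIDES:
        h = hs_ms[side]
        t = to_ms[side]
        for k in range(len(h) - 1):
            if t[k] < 0:
                continue
            steps.append({"side": side, "to_ms": int(t[k]), "hs_ms": int(h[k + 1])})
    steps.sort(key=lambda s: s["hs_ms"])
    n_steps = len(steps)

    # ---- per-step latent variables --------------------------------------
    p = np.empty(n_steps)
    z = rng.standard_normal(n_steps)
    p[0] = sigma_p * z[0]
    rho = params.ar1_rho
    for j in range(1, n_steps):
        p[j] = rho * p[j - 1] + math.sqrt(max(1.0 - rho * rho, 0.0)) * sigma_p * z[j]
    q = params.sigma_com_mode * rng.standard_normal(n_steps)
    e_fp = sigma_fp * rng.standard_normal(n_steps)
    zeta = params.sigma_emg * rng.standard_normal((n_steps, 3))
    zeta = np.maximum(zeta, -0.95)       # envelope amplitudes stay positive
    eta = sigma_cop * rng.standard_normal(n_steps)

    # EMG scalar targets: what the measurement chain is expected to return
    # (plateau level * rectified-carrier mean * early-stance duration)
    base = np.asarray(params.emg_base_level, dtype=float)
    early_s = 0.3 * stride_s
    scalars = base[None, :] * (1.0 + zeta) * _RECT_MEAN * early_s

    # injected single-stance CoP shifts
    muscle_part = (scalars - base[None, :] * _RECT_MEAN * early_s) @ gains_m
    cop_shift = beta_error * e_fp + muscle_part + eta

    # ---- foot placement chain -------------------------------------------
    fp_lat = params.step_width_mean + params.beta_pos * p + e_fp
    foot_y = {"right": -params.step_width_mean / 2.0,
              "left": params.step_width_mean / 2.0}
    y_new = np.empty(n_steps)
    y_stance = np.empty(n_steps)
    for j, st in enumerate(steps):
        side = st["side"]
        other = "left" if side == "right" else "right"
        y_stance[j] = foot_y[other]
        y_new[j] = foot_y[other] + _mirror_sign(side) * fp_lat[j]
        foot_y[side] = y_new[j]
        st["y_new"] = y_new[j]
        st["y_stance"] = y_stance[j]

    # ---- CoM mediolateral series (50 samples/s) --------------------------
    n_kin = int(dur_ms // 20) + 1
    kin_t = np.arange(n_kin) * _KIN_DT
    com_y = np.full(n_kin, np.nan)
    lam = params.beta_pos / params.beta_vel
    a = lam * _KIN_DT
    z1 = -a + math.sqrt(1.0 + a * a)     # |z1| < 1; z1 - 1/z1 = -2a exactly
    for j, st in enumerate(steps):
        to_s, hs_s = st["to_ms"] / 1000.0, st["hs_ms"] / 1000.0
        n_lo = int(math.ceil((to_s - _EDGE_MARGIN * _KIN_DT) / _KIN_DT - 1e-9))
        n_hi = int(math.floor((hs_s + _EDGE_MARGIN * _KIN_DT) / _KIN_DT + 1e-9))
        n_lo = max(n_lo, 0)
        n_hi = min(n_hi, n_kin - 1)
        idx = np.arange(n_lo, n_hi + 1)
        tau = (idx * _KIN_DT - to_s) / (hs_s - to_s)
        mode = np.power(z1, idx - n_lo)
        rel = _mean_swing_profile(tau, params.step_width_mean) + p[j] + q[j] * mode
        com_y[idx] = st["y_stance"] + _mirror_sign(st["side"]) * rel
        st["mode_origin"] = n_lo
    # bridge the double-support gaps linearly
    filled = np.flatnonzero(~np.isnan(com_y))
    com_y = np.interp(np.arange(n_kin), filled, com_y[filled])

    # ---- foot/ankle trajectories (50 samples/s) --------------------------
    ankle = {}
    stance_half_travel = speed_mps * (stance_ms / 1000.0) / 2.0
    for side in SIDES:
        h, t = hs_ms[side], to_ms[side]
        y_series = np.full(n_kin, np.nan)
        x_series = np.full(n_kin, np.nan)
        z_series = np.full(n_kin, 0.09)
        # stance segments: constant y, belt-driven x
        y_hold = (params.step_width_mean / 2.0) * _mirror_sign(side)
        placed = {int(st["hs_ms"]): st["y_new"] for st in steps if st["side"] == side}
        for k in range(len(h)):
            s_lo = max(int(h[k]), 0)
            s_hi = min(int(t[k]), dur_ms)
            if s_hi <= 0 or s_lo >= dur_ms:
                continue
            i_lo = int(math.ceil(s_lo / 20.0 - 1e-9))
            i_hi = int(math.floor(s_hi / 20.0 + 1e-9))
            i_hi = min(i_hi, n_kin - 1)
            if int(h[k]) in placed:
                y_hold = placed[int(h[k])]
            idx = np.arange(i_lo, i_hi + 1)
            y_series[idx] = y_hold
            x_series[idx] = stance_half_travel - speed_mps * (idx * _KIN_DT - s_lo / 1000.0)
        # swing: smooth blend between consecutive stance endpoints
        known = np.flatnonzero(~np.isnan(y_series))
        if known.size == 0:
            raise ConfigurationError("trial too short to contain any stance")
        gaps = np.flatnonzero(np.isnan(y_series))
        y_series = _smooth_fill(y_series)
        x_series = _smooth_fill(x_series)
        z_series[gaps] = 0.09 + 0.05  # coarse swing-foot lift marker
        ankle[side] = np.column_stack([x_series, y_series, z_series])

    landmarks = {}
    for side in SIDES:
        ank = ankle[side]
        inward = -_mirror_sign(side)     # toward the midline
        med = ank + np.array([0.0, 0.04 * inward, -0.02])
        lat = ank + np.array([0.0, -0.04 * inward, -0.02])
        cal = ank + np.array([-0.06, 0.0, -0.06])
        toe = ank + np.array([0.15, 0.0, -0.07])
        landmarks[f"{side}_medial_malleolus"] = med
        landmarks[f"{side}_lateral_malleolus"] = lat
        landmarks[f"{side}_calcaneus"] = cal
        landmarks[f"{side}_toe"] = toe

    # segment endpoints: mediolateral coordinates ride the body CoM so that
    # any mass-weighted combination reproduces com_y exactly (see methods)
    seg_geom = {
        "head": (1.55, 1.75), "trunk": (1.10, 1.55), "pelvis": (0.95, 1.10),
        "thigh_left": (0.50, 0.95), "thigh_right": (0.50, 0.95),
        "shank_left": (0.10, 0.50), "shank_right": (0.10, 0.50),
        "foot_left": (0.02, 0.10), "foot_right": (0.02, 0.10),
    }
    sway_x = 0.03 * np.sin(2.0 * np.pi * kin_t / stride_s)
    segments = {}
    for name, (z_lo, z_hi) in seg_geom.items():
        prox = np.column_stack([sway_x, com_y, np.full(n_kin, z_hi)])
        dist = np.column_stack([sway_x, com_y, np.full(n_kin, z_lo)])
        segments[name] = (prox, dist)

    # ---- per-belt forces and CoP (1000 samples/s) ------------------------
    n_force = dur_ms + 1
    force_t = np.arange(n_force) / FORCE_RATE
    body_weight = params.body_mass * GRAVITY
    step_by_hs = {(st["side"], st["hs_ms"]): (j, st) for j, st in enumerate(steps)}
    forces = {}
    for side in SIDES:
        fz = np.zeros(n_force)
        cop = np.full((n_force, 3), np.nan)
        for k in range(len(hs_ms[side])):
            s_lo, s_hi = int(hs_ms[side][k]), int(to_ms[side][k])
            if s_hi <= 0 or s_lo >= n_force:
                continue
            lo, hi = max(s_lo, 0), min(s_hi, n_force)
            u = np.arange(lo, hi) - s_lo
            dur = s_hi - s_lo
            ramp_in = np.clip(u / d1_ms, 0.0, 1.0)
            ramp_out = np.clip((dur - 1 - u) / d1_ms, 0.0, 1.0)
            shape = 0.5 - 0.5 * np.cos(np.pi * np.minimum(ramp_in, ramp_out))
            fz[lo:hi] = body_weight * (0.15 + 0.85 * shape)
            # lateral CoP in the local foot frame (lateral positive)
            key = (side, s_lo)
            ml = np.zeros(hi - lo)
            if key in step_by_hs:
                j, st = step_by_hs[key]
                ss_lo, ss_hi = s_lo + d1_ms, s_lo + half_ms
                n_ss = ss_hi - ss_lo + 1
                m = np.arange(lo, hi) - ss_lo
                ramp = np.clip(m / (n_ss - 1.0), 0.0, 1.0)
                ml = cop_shift[j] * 2.0 * ramp
                y_foot = st["y_new"]
            else:
                y_foot = params.step_width_mean / 2.0 * _mirror_sign(side)
                for st in steps:   # foot position from the most recent placement
                    if st["side"] == side and st["hs_ms"] < s_lo:
                        y_foot = st["y_new"]
            prog = -0.05 + 0.23 * (np.arange(lo, hi) - s_lo) / max(dur - 1, 1)
            x_ankle = stance_half_travel - speed_mps * (np.arange(lo, hi) - s_lo) / 1000.0
            cop[lo:hi, 0] = x_ankle + prog
            cop[lo:hi, 1] = y_foot + _mirror_sign(side) * ml
            cop[lo:hi, 2] = 0.0
        forces[side] = {"fz": fz, "cop": cop}

    # ---- raw EMG (2000 samples/s) ----------------------------------------
    emg_t = None
    emg = None
    if params.synthesize_emg:
        n_emg = 2 * dur_ms + 1
        emg_t = np.arange(n_emg) / EMG_RATE
        emg = {}
        edge = 60                       # 30 ms raised-cosine burst edges
        for side in SIDES:
            for m_i, muscle in enumerate(MUSCLES):
                env = np.full(n_emg, 0.05 * base[m_i])
                for st in steps:
                    if st["side"] != side:
                        continue
                    j = step_by_hs[(side, st["hs_ms"])][0]
                    lo = 2 * st["hs_ms"]
                    hi = lo + int(round(0.3 * t_ms * 2))
                    lo, hi = max(lo, 0), min(hi, n_emg)
                    if hi <= lo:
                        continue
                    level = base[m_i] * (1.0 + zeta[j, m_i])
                    prof = np.full(hi - lo, level)
                    k = min(edge, (hi - lo) // 2)
                    if k > 0:
                        w = 0.5 - 0.5 * np.cos(np.pi * np.arange(k) / k)
                        prof[:k] = 0.05 * base[m_i] + (level - 0.05 * base[m_i]) * w
                        prof[-k:] = 0.05 * base[m_i] + (level - 0.05 * base[m_i]) * w[::-1]
                    env[lo:hi] = prof
                carrier = rng.standard_normal(n_emg)
                emg[(side, muscle)] = env * carrier + 0.01 * base[m_i] * rng.standard_normal(n_emg)

    # ---- truth log --------------------------------------------------------
    step_rows = pd.DataFrame({
        "step_index": np.arange(n_steps),
        "side": [st["side"] for st in steps],
        "t_toeoff": [st["to_ms"] / 1000.0 for st in steps],
        "t_heelstrike": [st["hs_ms"] / 1000.0 for st in steps],
        "t_ss_start": [(st["hs_ms"] + d1_ms) / 1000.0 for st in steps],
        "t_ss_end": [(st["hs_ms"] + half_ms) / 1000.0 for st in steps],
        "fp_lat": fp_lat,
        "com_offset": p,
        "com_mode": q,
        "fp_error": e_fp,
        "cop_shift": cop_shift,
        "emg_scalar_pl": scalars[:, 0],
        "emg_scalar_ta": scalars[:, 1],
        "emg_scalar_so": scalars[:, 2],
    })
    swing_ms = t_ms - stance_ms
    # a heel strike is observable only if its preceding swing started in-record
    clip_hs = lambda arr: arr[(arr >= swing_ms) & (arr <= dur_ms)] / 1000.0
    clip_to = lambda arr: arr[(arr >= 0) & (arr <= dur_ms)] / 1000.0
    truth = TruthLog(
        heel_strikes={s: clip_hs(hs_ms[s].astype(float)) for s in SIDES},
        toe_offs={s: clip_to(to_ms[s].astype(float)) for s in SIDES},
        steps=step_rows,
        coefficients={
            "beta_pos": params.beta_pos,
            "beta_vel": params.beta_vel,
            "beta_error": beta_error,
            "muscle_gains_cm": tuple(gains_cm),
            "sigma_fp": sigma_fp,
            "sigma_cop": sigma_cop,
            "stride_time_s": stride_s,
            "speed_mps": speed_mps,
            "double_support_s": d1_ms / 1000.0,
        },
    )
    return SynthTrial(
        params=params,
        kin_t=kin_t,
        landmarks=landmarks,
        segments=segments,
        force_t=force_t,
        forces=forces,
        emg_t=emg_t,
        emg=emg,
        truth=truth,
        body_weight=body_weight,
    )


def _smooth_fill(series: np.ndarray) -> np.ndarray:
    """Fill NaN gaps with a C1 (smoothstep-blended) interpolant."""
    out = series.copy()
    isnan = np.isnan(out)
    if not isnan.any():
        return out
    known = np.flatnonzero(~isnan)
    first, last = known[0], known[-1]
    out[:first] = out[first]
    out[last + 1:] = out[last]
    # blend across each interior gap with a smoothstep to avoid velocity spikes
    gap_starts = np.flatnonzero(~isnan[:-1] & isnan[1:])
    for g0 in gap_starts:
        g1 = g0 + 1
        while g1 < len(out) and np.isnan(out[g1]):
            g1 += 1
        if g1 >= len(out):
            break
        u = (np.arange(g0 + 1, g1) - g0) / (g1 - g0)
        s = u * u * (3.0 - 2.0 * u)
        out[g0 + 1:g1] = out[g0] + (out[g1] - out[g0]) * s
    return out


def cohort_params(
    n_participants: int,
    design: Sequence[Tuple[str, str]],
    base_params: SynthParams,
    seed: int,
) -> Dict[Tuple[int, str, str], SynthParams]:
    """Per-(participant, condition, speed) generator parameters.

    Each participant gets an independent random stream; coefficients are
    perturbed around ``base_params`` (~10% between-subject SD), anthropometry
    around typical adult values, and slow-speed trials get a proportionally
    longer stride time. The returned mapping is what :func:`generate_cohort`
    materializes; callers that cannot hold a cohort in memory can stream
    trials from it one cell at a time.
    """
    if n_participants < 0:
        raise ConfigurationError("n_participants must be >= 0")
    if len(design) == 0:
        raise ConfigurationError("design must contain at least one cell")
    if len(set(design)) != len(design):
        raise ConfigurationError("duplicate design cells")
    for cond, speed in design:
        if cond not in ("steady", "ankle_constrained", "fp_constrained"):
            raise ConfigurationError(f"unknown condition {cond!r}")
        if speed not in ("normal", "slow"):
            raise ConfigurationError(f"unknown speed {speed!r}")
    out: Dict[Tuple[int, str, str], SynthParams] = {}
    root = np.random.SeedSequence(seed)
    for pid, pseq in enumerate(root.spawn(max(n_participants, 0))):
        prng = np.random.default_rng(pseq)
        jit = lambda v, s=0.1: v * (1.0 + s * prng.standard_normal())
        leg = float(np.clip(jit(base_params.leg_length, 0.05), 0.75, 1.1))
        beta_pos = jit(base_params.beta_pos)
        beta_vel = jit(base_params.beta_vel)
        beta_error = jit(base_params.beta_error)
        gains = tuple(jit(g) for g in base_params.muscle_gains)
        stride_jitter = 1.0 + 0.03 * prng.standard_normal()
        trial_seeds = prng.integers(0, 2**31 - 1, size=len(design))
        for cell_i, (cond, speed) in enumerate(design):
            stride = base_params.stride_time * stride_jitter
            if speed == "slow":
                stride *= 1.22
            out[(pid, cond, speed)] = replace(
                base_params,
                leg_length=leg,
                beta_pos=beta_pos,
                beta_vel=beta_vel,
                beta_error=beta_error,
                muscle_gains=gains,
                stride_time=stride,
                condition=cond,
                speed=speed,
                seed=int(trial_seeds[cell_i]),
            )
    return out


def generate_cohort(
    n_participants: int,
    design: Sequence[Tuple[str, str]],
    base_params: SynthParams,
    seed: int,
) -> Dict[Tuple[int, str, str], SynthTrial]:
    """Generate every trial of a (participant x condition x speed) cohort."""
    return {
        key: generate_trial(p)
        for key, p in cohort_params(n_participants, design, base_params, seed).items()
    }
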