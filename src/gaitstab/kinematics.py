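"""Center of mass, local foot frames, CoP shifts, and step-table assembly.

All internal units are meters and seconds; the reporting layer converts
CoP/foot-placement quantities to centimeters. The mediolateral coordinate of
every per-step quantity follows the lateral-positive convention: left-side
steps are mirrored so that "too lateral" is positive for both feet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SWING_SAMPLES
from .exceptions import DegenerateGeometryError, InsufficientDataError

_LATERAL_SIGN = {"left": 1.0, "right": -1.0}


@dataclass
class CoMSeries:
    """Body-CoM mediolateral position/velocity on the kinematic clock."""

    t: np.ndarray
    pos: np.ndarray      # ML position (m)
    vel: np.ndarray      # ML velocity (m/s), central differences interior


@dataclass
class FootFrame:
    """Local anatomical foot frame.

    ``axes`` rows are (forward, mediolateral, vertical); the ML row is
    re-signed so that +ML is lateral for either foot, and the forward row is
    flipped with it so the frame stays right-handed (only the ML coordinate
    is consumed downstream).
    """

    side: str
    origin: np.ndarray
    axes: np.ndarray     # 3x3, rows orthonormal

    @property
    def lateral_axis(self) -> np.ndarray:
        return self.axes[1]

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.axes.T

    def to_global(self, points_local: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points_local) @ self.axes + self.origin


@dataclass
class StepTable:
    """One row per step: everything the three regression models consume.

    All columns are demeaned per trial (predictors per sample index); the
    pre-demeaning means are kept for reporting. ``com_pos``/``com_vel`` hold
    the swing-phase CoM state relative to the stance foot, resampled to 51
    samples (sample 1 = toe-off ... sample 51 = heel strike).
    """

    side: np.ndarray
    stride_index: np.ndarray
    fp: np.ndarray                  # demeaned ML foot placement (m)
    com_pos: np.ndarray             # (n, 51), demeaned per index
    com_vel: np.ndarray             # (n, 51), demeaned per index
    cop_shift: np.ndarray           # demeaned single-stance CoP shift (m)
    emg: Optional[np.ndarray] = None  # (n, 3) demeaned scalars (PL, TA, SO)
    fp_mean: float = 0.0
    cop_shift_mean: float = 0.0

    def __len__(self) -> int:
        return len(self.fp)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "side": self.side,
            "stride_index": self.stride_index,
            "fp": self.fp,
            "cop_shift": self.cop_shift,
        })
        if self.emg is not None:
            df[["emg_pl", "emg_ta", "emg_so"]] = self.emg
        return df


def compute_com(
    segments: Dict[str, Tuple[np.ndarray, np.ndarray]],
    anthropometry: pd.DataFrame,
    t: np.ndarray,
) -> CoMSeries:
    """Mass-weighted body CoM (ML) from segment endpoint trajectories.

    Each segment's CoM sits at ``com_fraction`` along its proximal->distal
    axis; the body CoM is the mass-fraction weighted sum. Velocity follows by
    numerical differentiation at the kinematic rate (central differences in
    the interior, one-sided at the edges).
    """
    t = np.asarray(t, dtype=float)
    total = anthropometry["mass_fraction"].sum()
    if total <= 0:
        raise ValueError("total segment mass is zero")
    missing = [s for s in anthropometry["segment"] if s not in segments]
    if missing:
        raise KeyError(f"missing segment trajectories: {', '.join(missing)}")
    com = np.zeros(len(t))
    for _, row in anthropometry.iterrows():
        prox, dist = segments[row["segment"]]
        prox = np.atleast_2d(np.asarray(prox, dtype=float))
        dist = np.atleast_2d(np.asarray(dist, dtype=float))
        seg_ml = prox[:, 1] + row["com_fraction"] * (dist[:, 1] - prox[:, 1])
        com = com + (row["mass_fraction"] / total) * seg_ml
    dt = t[1] - t[0]
    vel = np.gradient(com, dt)
    return CoMSeries(t=t, pos=com, vel=vel)


def build_foot_frame(
    medial_malleolus: np.ndarray,
    lateral_malleolus: np.ndarray,
    calcaneus: np.ndarray,
    toe: np.ndarray,
    side: str,
    origin: Optional[np.ndarray] = None,
) -> FootFrame:
    """Anatomical foot frame from four bony landmarks.

    The ankle joint center is the malleolar midpoint; a temporary forward
    axis runs calcaneus->toe; the ML axis is (calcaneus->ankle) x forward;
    vertical is forward x ML; forward is re-derived as ML x vertical. The ML
    axis is then re-signed (using the malleolar medial->lateral direction) so
    +ML is lateral for the given side. Default origin: ankle joint center.
    """
    med = np.asarray(medial_malleolus, dtype=float)
    lat = np.asarray(lateral_malleolus, dtype=float)
    cal = np.asarray(calcaneus, dtype=float)
    toe = np.asarray(toe, dtype=float)
    ankle = 0.5 * (med + lat)
    tmp_fwd = toe - cal
    ml = np.cross(cal_to_ankle := (ankle - cal), tmp_fwd)
    n_ml = np.linalg.norm(ml)
    if n_ml < 1e-9 or np.linalg.norm(tmp_fwd) < 1e-9:
        raise DegenerateGeometryError("foot landmarks are collinear")
    ml = ml / n_ml
    vert = np.cross(tmp_fwd, ml)
    vert = vert / np.linalg.norm(vert)
    fwd = np.cross(ml, vert)
    # lateral-positive convention for both feet; flip forward with ML so the
    # frame stays right-handed
    if np.dot(ml, lat - med) < 0:
        ml = -ml
        fwd = -fwd
    axes = np.vstack([fwd, ml, vert])
    if origin is None:
        origin = ankle
    return FootFrame(side=side, origin=np.asarray(origin, dtype=float), axes=axes)


def cop_to_local(cop_global: np.ndarray, frame: FootFrame) -> np.ndarray:
    """Local mediolateral CoP (m, lateral positive); NaN samples propagate."""
    cop = np.atleast_2d(np.asarray(cop_global, dtype=float))
    return (cop - frame.origin) @ frame.lateral_axis


def compute_cop_shift(
    local_ml: np.ndarray,
    t: np.ndarray,
    window: Tuple[float, float],
) -> float:
    """Average single-stance ML CoP shift w.r.t. the window's first sample.

    ``window`` is the single-stance interval (contralateral toe-off to
    contralateral heel strike). NaN samples inside the window are dropped;
    at least two finite samples (including the first) are required.
    """
    t0, t1 = window
    if not (t1 > t0):
        raise InsufficientDataError("empty single-stance window")
    eps = 1e-9
    mask = (t >= t0 - eps) & (t <= t1 + eps)
    vals = np.asarray(local_ml, dtype=float)[mask]
    if vals.size < 2:
        raise InsufficientDataError("single-stance window has fewer than 2 samples")
    if not np.isfinite(vals[0]):
        raise InsufficientDataError("CoP undefined at single-stance onset")
    finite = vals[np.isfinite(vals)]
    if finite.size < 2:
        raise InsufficientDataError("single-stance window is mostly undefined")
    return float(np.mean(finite - vals[0]))


def resample_step(
    t: np.ndarray,
    series: np.ndarray,
    t_start: float,
    t_end: float,
    n: int = SWING_SAMPLES,
) -> np.ndarray:
    """Linear time-normalization of a series to ``n`` samples over a window."""
    tau = np.linspace(t_start, t_end, n)
    return np.interp(tau, t, series)


def compute_fp_and_predictors(
    com: CoMSeries,
    foot_ml: Dict[str, np.ndarray],
    windows: pd.DataFrame,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-step foot placement and 51-sample CoM-state predictors.

    Foot placement is the ML position of the newly placed foot at mid-stance
    minus the stance-foot ML position (referenced at the step's heel strike,
    when the contralateral foot is still planted). Predictors are the
    swing-phase CoM state relative to the stance-foot series, linearly
    resampled toe-off -> heel strike to 51 samples. Left steps are mirrored
    to the lateral-positive convention before pooling; everything is then
    demeaned (foot placement over steps, predictors per sample index).

    Returns ``(fp, com_pos, com_vel, fp_mean)`` with fp demeaned.
    """
    t = com.t
    dt = t[1] - t[0]
    foot_ml = {s: np.asarray(y, dtype=float) for s, y in foot_ml.items()}
    foot_vel = {s: np.gradient(y, dt) for s, y in foot_ml.items()}
    n_steps = len(windows)
    fp = np.empty(n_steps)
    pos = np.empty((n_steps, SWING_SAMPLES))
    vel = np.empty((n_steps, SWING_SAMPLES))
    sides = windows["side"].to_numpy()
    to_t = windows["toe_off_t"].to_numpy()
    hs_t = windows["heel_strike_t"].to_numpy()
    ms_t = windows["midstance_t"].to_numpy()
    if to_t.size and (to_t.min() < t[0] or ms_t.max() > t[-1]):
        bad = hs_t[int(np.argmax((to_t < t[0]) | (ms_t > t[-1])))]
        raise InsufficientDataError(
            f"step at heel strike {bad:.3f}s outside kinematic support"
        )
    frac = np.linspace(0.0, 1.0, SWING_SAMPLES)
    for side in ("left", "right"):
        rows = np.flatnonzero(sides == side)
        if rows.size == 0:
            continue
        other = "left" if side == "right" else "right"
        sgn = _LATERAL_SIGN[side]
        tau = to_t[rows, None] + (hs_t[rows] - to_t[rows])[:, None] * frac
        flat = tau.ravel()
        pos[rows] = sgn * (np.interp(flat, t, com.pos)
                           - np.interp(flat, t, foot_ml[other])).reshape(-1, SWING_SAMPLES)
        vel[rows] = sgn * (np.interp(flat, t, com.vel)
                           - np.interp(flat, t, foot_vel[other])).reshape(-1, SWING_SAMPLES)
        y_new = np.interp(ms_t[rows], t, foot_ml[side])
        y_stance = np.interp(hs_t[rows], t, foot_ml[other])
        fp[rows] = sgn * (y_new - y_stance)
    fp_mean = float(fp.mean())
    return fp - fp_mean, pos - pos.mean(axis=0), vel - vel.mean(axis=0), fp_mean
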