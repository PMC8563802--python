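"""Gait event detection and step/stride windowing.

Heel strikes and toe-offs are detected primarily from per-belt vertical
force threshold crossings (dual-belt treadmills give per-foot forces). A
fallback detector recovers the same events from the rapid mediolateral
transfers of the total-CoP "butterfly" trace when only a single combined
CoP is available. Events are reported at the sample immediately after the
threshold crossing; at treadmill rates (>= 1000 samples/s) sub-sample
interpolation buys nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .config import EARLY_STANCE_FRACTION, N_STRIDES_DEFAULT, SIDES
from .exceptions import InsufficientDataError

_STEP_COLUMNS = [
    "side", "toe_off_t", "heel_strike_t", "midswing_t", "midstance_t",
    "stance_end_t", "stride_end_t", "stride_time",
    "ss_start_t", "ss_end_t", "early_start_t", "early_end_t",
]


@dataclass
class GaitEvents:
    """Per-side heel-strike and toe-off times (s), ascending."""

    heel_strikes: Dict[str, np.ndarray]
    toe_offs: Dict[str, np.ndarray]

    def is_empty(self) -> bool:
        return all(len(self.heel_strikes[s]) == 0 and len(self.toe_offs[s]) == 0
                   for s in self.heel_strikes)

    def validate(self) -> None:
        for s in self.heel_strikes:
            for arr in (self.heel_strikes[s], self.toe_offs[s]):
                if np.any(np.diff(arr) <= 0):
                    raise ValueError(f"events on side {s!r} not strictly increasing")
            # every toe-off must be followed by a heel strike before the next toe-off
            to, hs = self.toe_offs[s], self.heel_strikes[s]
            for i, t in enumerate(to[:-1]):
                nxt = hs[(hs > t) & (hs < to[i + 1])]
                if len(nxt) == 0:
                    raise ValueError(
                        f"toe-off at {t:.3f}s on side {s!r} has no matching heel strike"
                    )


@dataclass
class StepWindows:
    """Tidy step table: one row per step with all derived analysis windows."""

    table: pd.DataFrame
    truncated: bool = False          # fewer strides available than requested
    n_strides: int = 0

    def __len__(self) -> int:
        return len(self.table)


def _check_uniform(t: np.ndarray, min_rate: float = 100.0) -> float:
    if len(t) < 2:
        raise InsufficientDataError("time series too short")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform sampling")
    rate = 1.0 / dt[0]
    if rate < min_rate:
        raise ValueError(f"sampling rate {rate:.1f}/s below required {min_rate}/s")
    return rate


def detect_gait_events(
    t: np.ndarray,
    belt_fz: Dict[str, np.ndarray],
    body_weight: float,
    threshold_fraction: float = 0.05,
) -> GaitEvents:
    """Detect heel strikes / toe-offs from per-belt vertical forces.

    A heel strike is the first sample at or above ``threshold_fraction`` of
    body weight after an unloaded period; a toe-off is the first sample
    below it after a loaded period. Belts loaded at the start or end of the
    record yield no event there (partial cycles are dropped by not being
    invented).
    """
    t = np.asarray(t, dtype=float)
    _check_uniform(t)
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    thr = threshold_fraction * body_weight
    hs, to = {}, {}
    for side, fz in belt_fz.items():
        fz = np.asarray(fz, dtype=float)
        if len(fz) != len(t):
            raise ValueError(f"force series on side {side!r} does not match time base")
        above = fz >= thr
        rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
        falling = np.flatnonzero(above[:-1] & ~above[1:]) + 1
        hs[side] = t[rising]
        to[side] = t[falling]
    return GaitEvents(heel_strikes=hs, toe_offs=to)


def detect_gait_events_from_cop(
    t: np.ndarray,
    cop_ml: np.ndarray,
    velocity_factor: float = 3.0,
    strong_factor: float = 10.0,
) -> GaitEvents:
    """Fallback detector from the total-CoP butterfly trace.

    The combined CoP dwells under the stance foot during single stance and
    sweeps rapidly across during double support. Heel strikes are the onsets
    and toe-offs the offsets of those sweeps; the sweep direction assigns the
    sides (ML positive toward the left). Thresholds adapt to the trace:
    a candidate run exceeds ``velocity_factor`` times the median absolute ML
    CoP velocity (dominated by single stance), and is kept as a sweep only if
    it also contains a sample above ``strong_factor`` times that median —
    the hysteresis keeps slow within-stance CoP ramps from masquerading as,
    or bridging, belt-to-belt transfers.
    """
    t = np.asarray(t, dtype=float)
    _check_uniform(t)
    cop_ml = np.asarray(cop_ml, dtype=float)
    dt = t[1] - t[0]
    v = np.gradient(cop_ml, dt)
    med = np.median(np.abs(v[np.isfinite(v)]))
    if med == 0 or not np.isfinite(med):
        return GaitEvents({s: np.array([]) for s in SIDES},
                          {s: np.array([]) for s in SIDES})
    fast = np.abs(v) > velocity_factor * med
    strong = np.abs(v) > strong_factor * med
    idx = np.flatnonzero(fast)
    if idx.size == 0:
        return GaitEvents({s: np.array([]) for s in SIDES},
                          {s: np.array([]) for s in SIDES})
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    keep = np.array([strong[s0:s1 + 1].any() for s0, s1 in zip(starts, ends)])
    starts, ends = starts[keep], ends[keep]
    hs = {s: [] for s in SIDES}
    to = {s: [] for s in SIDES}
    for s0, s1 in zip(starts, ends):
        if cop_ml[s1] == cop_ml[s0]:
            continue
        toward_left = cop_ml[s1] > cop_ml[s0]
        dest = "left" if toward_left else "right"
        src = "right" if toward_left else "left"
        hs[dest].append(t[s0])
        to[src].append(t[s1])
    return GaitEvents({s: np.asarray(hs[s]) for s in SIDES},
                      {s: np.asarray(to[s]) for s in SIDES})


def segment_strides(
    events: GaitEvents,
    select_n: int = N_STRIDES_DEFAULT,
    early_stance_fraction: float = EARLY_STANCE_FRACTION,
) -> StepWindows:
    """Derive per-step analysis windows and keep the final ``select_n`` strides.

    A step runs from toe-off to the next heel strike of the swinging foot;
    mid-swing is 50% of the step. The single-stance window of the placed foot
    runs from the contralateral toe-off to the contralateral heel strike;
    early stance covers the first ``early_stance_fraction`` of the stride
    (heel strike to next same-side heel strike). Steps lacking any of those
    boundary events (trial edges) are dropped.
    """
    rows = []
    sides = list(events.heel_strikes)
    for side in sides:
        other = [s for s in sides if s != side]
        other = other[0] if other else None
        hs = np.asarray(events.heel_strikes[side], dtype=float)
        to = np.asarray(events.toe_offs[side], dtype=float)
        o_hs = np.asarray(events.heel_strikes[other], dtype=float) if other else np.array([])
        o_to = np.asarray(events.toe_offs[other], dtype=float) if other else np.array([])
        for t_to in to:
            nxt = hs[hs > t_to]
            if len(nxt) == 0:
                continue                       # trailing toe-off: incomplete step
            t_hs = nxt[0]
            later_to = to[to > t_hs]
            later_hs = hs[hs > t_hs]
            if len(later_to) == 0 or len(later_hs) == 0:
                continue                       # no stance end / stride end
            stance_end = later_to[0]
            stride_end = later_hs[0]
            ss_to = o_to[(o_to > t_hs) & (o_to < stance_end)]
            if len(ss_to) == 0:
                continue
            ss_start = ss_to[0]
            ss_hs = o_hs[(o_hs > ss_start) & (o_hs <= stance_end)]
            if len(ss_hs) == 0:
                continue
            ss_end = ss_hs[0]
            stride_time = stride_end - t_hs
            rows.append({
                "side": side,
                "toe_off_t": t_to,
                "heel_strike_t": t_hs,
                "midswing_t": 0.5 * (t_to + t_hs),
                "midstance_t": t_hs + 0.5 * (stance_end - t_hs),
                "stance_end_t": stance_end,
                "stride_end_t": stride_end,
                "stride_time": stride_time,
                "ss_start_t": ss_start,
                "ss_end_t": ss_end,
                "early_start_t": t_hs,
                "early_end_t": t_hs + early_stance_fraction * stride_time,
            })
    if not rows:
        return StepWindows(pd.DataFrame(columns=_STEP_COLUMNS), truncated=select_n > 0)
    df = pd.DataFrame(rows).sort_values("heel_strike_t").reset_index(drop=True)
    n_strides_avail = len(df) // 2
    want_steps = 2 * select_n
    truncated = n_strides_avail < select_n
    if len(df) > want_steps:
        df = df.iloc[len(df) - want_steps:].reset_index(drop=True)
    return StepWindows(df, truncated=truncated,
                       n_strides=min(select_n, n_strides_avail))
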