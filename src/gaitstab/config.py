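"""Protocol constants, run configuration and the anthropometric table.

All defaults reproduce the study protocol choices where the protocol states
them (sampling rates, stride counts, normalization lengths, filter corners,
the walking-speed rule). Quantities the protocol leaves open (anthropometric
regression coefficients, double-support fraction) are shipped as replaceable
configuration with standard literature values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

# --- sampling rates (samples/s) ---
KINEMATIC_RATE = 50.0
FORCE_RATE = 1000.0
EMG_RATE = 2000.0

# --- stride/step protocol constants ---
N_STRIDES_DEFAULT = 200          # final consecutive strides analyzed per trial
SWING_SAMPLES = 51               # step (toe-off -> heel strike) resampled length
MIDSWING_INDEX = 25              # 1-based index used for the ankle-strategy model
HEELSTRIKE_INDEX = 51            # 1-based terminal-swing index
STRIDE_EMG_SAMPLES = 1000        # stride-normalized EMG length
EARLY_STANCE_FRACTION = 0.3      # heel strike -> mid-stance = 0-30% of the stride

# --- EMG filter corners (Hz) ---
EMG_HIGHPASS_HZ = 20.0
EMG_LOWPASS_HZ = 50.0

# --- walking speed rule: v = c * sqrt(leg length) m/s ---
SPEED_COEFFICIENTS = {"normal": 1.25, "slow": 0.63}

# --- Bayesian default prior width on the standardized effect ---
RSCALE_DEFAULT = math.sqrt(2.0) / 2.0

CONDITIONS = ("steady", "ankle_constrained", "fp_constrained")
SPEEDS = ("normal", "slow")
SIDES = ("left", "right")
MUSCLES = ("pl", "ta", "so")     # peroneus longus, tibialis anterior, soleus


def walking_speed(leg_length_m: float, speed: str) -> float:
    """Treadmill belt speed (m/s) for a leg length, per the protocol rule."""
    try:
        c = SPEED_COEFFICIENTS[speed]
    except KeyError:
        raise ValueError(f"unknown speed condition {speed!r}") from None
    if leg_length_m <= 0:
        raise ValueError("leg length must be positive")
    return c * math.sqrt(leg_length_m)


def default_anthropometry() -> pd.DataFrame:
    """Per-segment mass fractions and longitudinal CoM locations.

    Standard adult cadaver-based values (Dempster lineage). ``mass_fraction``
    is the segment mass as a fraction of body mass; ``com_fraction`` locates
    the segment CoM along the proximal->distal longitudinal axis. The table is
    plain configuration: replace it with subject-specific regression output
    when available.
    """
    rows = [
        # segment, mass fraction, CoM fraction (proximal -> distal)
        ("head", 0.081, 0.50),
        ("trunk", 0.497, 0.50),
        ("pelvis", 0.142, 0.50),
        ("thigh_left", 0.100, 0.433),
        ("thigh_right", 0.100, 0.433),
        ("shank_left", 0.0465, 0.433),
        ("shank_right", 0.0465, 0.433),
        ("foot_left", 0.0145, 0.50),
        ("foot_right", 0.0145, 0.50),
    ]
    df = pd.DataFrame(rows, columns=["segment", "mass_fraction", "com_fraction"])
    # normalize so fractions sum to 1 exactly
    df["mass_fraction"] = df["mass_fraction"] / df["mass_fraction"].sum()
    return df


@dataclass(frozen=True)
class RunConfig:
    """End-to-end analysis configuration.

    Defaults reproduce the protocol where it states a choice; everything is
    overridable per run.
    """

    select_n_strides: int = N_STRIDES_DEFAULT
    emg_highpass_hz: float = EMG_HIGHPASS_HZ
    emg_lowpass_hz: float = EMG_LOWPASS_HZ
    i_used: tuple[int, ...] = (MIDSWING_INDEX, HEELSTRIKE_INDEX)
    subset: str = "all"                  # {all, medial_only, lateral_only}
    rscale: float = RSCALE_DEFAULT
    force_threshold_fraction: float = 0.05  # heel-strike/toe-off force threshold
    early_stance_fraction: float = EARLY_STANCE_FRACTION
    seed: int = 0
    output_dir: str = "gaitstab_out"

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
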