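"""EMG envelope processing and per-step early-stance scalars.

Raw surface EMG is high-pass filtered at 20 Hz (movement artifact), full-wave
rectified, and low-pass filtered at 50 Hz into a linear envelope; filters are
zero-phase second-order recursive filters (effective fourth order). Each
stride (heel strike to next same-side heel strike) is time-normalized to
1000 samples, and the per-stride scalar is the median envelope over early
stance (the first 30% of the stride, heel strike to mid-stance) multiplied
by that episode's duration in seconds.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import signal

from .config import EARLY_STANCE_FRACTION, EMG_HIGHPASS_HZ, EMG_LOWPASS_HZ, STRIDE_EMG_SAMPLES
from .exceptions import InsufficientDataError


def process_emg(
    raw: np.ndarray,
    fs: float,
    highpass_hz: float = EMG_HIGHPASS_HZ,
    lowpass_hz: float = EMG_LOWPASS_HZ,
) -> np.ndarray:
    """Linear envelope: 20 Hz high-pass, rectify, 50 Hz low-pass (zero phase).

    The low-pass of a rectified signal can undershoot slightly; the envelope
    is clipped at zero to honor its non-negativity.
    """
    raw = np.asarray(raw, dtype=float)
    if fs <= 2 * max(highpass_hz, lowpass_hz):
        raise ValueError("sampling rate too low for the filter corners")
    sos_hp = signal.butter(2, highpass_hz, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.butter(2, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    min_len = 3 * 6 * 2  # three times the effective (forward+backward) filter length
    if raw.size < min_len:
        raise InsufficientDataError(
            f"EMG record of {raw.size} samples is too short to filter"
        )
    env = signal.sosfiltfilt(sos_lp, np.abs(signal.sosfiltfilt(sos_hp, raw)))
    return np.clip(env, 0.0, None)


def stride_normalize(
    env: np.ndarray,
    t: np.ndarray,
    strides: Sequence[Tuple[float, float]],
    n: int = STRIDE_EMG_SAMPLES,
) -> np.ndarray:
    """Time-normalize the envelope of each stride to ``n`` samples.

    ``strides`` holds (heel strike, next same-side heel strike) intervals.
    """
    t = np.asarray(t, dtype=float)
    env = np.asarray(env, dtype=float)
    out = np.empty((len(strides), n))
    for i, (t0, t1) in enumerate(strides):
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9 or not t1 > t0:
            raise InsufficientDataError(
                f"stride {i} [{t0:.3f}, {t1:.3f}]s outside EMG support"
            )
        out[i] = np.interp(np.linspace(t0, t1, n), t, env)
    return out


def emg_scalar(
    stride_env: np.ndarray,
    stride_durations: np.ndarray,
    early_fraction: float = EARLY_STANCE_FRACTION,
) -> np.ndarray:
    """Early-stance scalar per stride: median envelope x episode duration (s).

    Uses the first ``early_fraction`` of the 1000-sample normalized stride
    (heel strike to mid-stance); the duration factor is the same fraction of
    the measured stride time. Demeaning across strides is left to the
    step-table assembly so that subsets can be re-demeaned consistently.
    """
    stride_env = np.atleast_2d(np.asarray(stride_env, dtype=float))
    stride_durations = np.atleast_1d(np.asarray(stride_durations, dtype=float))
    k = int(round(early_fraction * stride_env.shape[1]))
    med = np.median(stride_env[:, :k], axis=1)
    return med * (early_fraction * stride_durations)
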