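"""Event detection and step segmentation."""

import numpy as np
import pandas as pd
import pytest

from gaitstab import GaitEvents, SynthParams, detect_gait_events, generate_trial, segment_strides
from gaitstab.events import detect_gait_events_from_cop


def _periodic_events(n_strides, stride=1.0, t0=1.0, swing=0.4):
    """Perfectly periodic alternating gait events."""
    stance = stride - swing
    r_hs = t0 + stride * np.arange(n_strides + 1)
    l_hs = r_hs + stride / 2.0
    return GaitEvents(
        heel_strikes={"right": r_hs, "left": l_hs},
        toe_offs={"right": r_hs + stance, "left": l_hs + stance},
    )


def test_quiet_standing_yields_no_events():
    t = np.arange(0, 5, 0.001)
    const = np.full(t.size, 400.0)
    ev = detect_gait_events(t, {"left": const, "right": const}, body_weight=700.0)
    assert ev.is_empty()
    ev0 = detect_gait_events(t, {"left": 0 * const, "right": 0 * const}, 700.0)
    assert ev0.is_empty()


def test_single_support_transfer_gives_one_hs_and_one_to():
    t = np.arange(0, 2, 0.001)
    left = np.where(t < 1.0, 700.0, 0.0)
    right = np.where(t >= 1.0, 700.0, 0.0)
    ev = detect_gait_events(t, {"left": left, "right": right}, 700.0)
    assert list(ev.heel_strikes["right"]) == [pytest.approx(1.0)]
    assert list(ev.toe_offs["left"]) == [pytest.approx(1.0)]
    assert len(ev.heel_strikes["left"]) == 0 and len(ev.toe_offs["right"]) == 0


def test_nonuniform_sampling_rejected():
    t = np.array([0.0, 0.001, 0.003, 0.004])
    with pytest.raises(ValueError):
        detect_gait_events(t, {"left": np.zeros(4), "right": np.zeros(4)}, 700.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_detection_matches_truth_within_10ms(seed):
    trial = generate_trial(SynthParams(n_strides=20, seed=seed, synthesize_emg=False))
    ev = detect_gait_events(trial.force_t,
                            {s: trial.forces[s]["fz"] for s in trial.forces},
                            trial.body_weight)
    for side in ("left", "right"):
        for det, tru in ((ev.heel_strikes[side], trial.truth.heel_strikes[side]),
                         (ev.toe_offs[side], trial.truth.toe_offs[side])):
            assert all(np.min(np.abs(det - x)) <= 0.010 for x in tru)
            assert all(np.min(np.abs(tru - x)) <= 0.010 for x in det)


def test_butterfly_fallback_recovers_events():
    """Total-CoP sweeps: onsets are heel strikes, offsets are toe-offs."""
    trial = generate_trial(SynthParams(n_strides=20, seed=2, synthesize_emg=False))
    fzl = trial.forces["left"]["fz"]
    fzr = trial.forces["right"]["fz"]
    total = fzl + fzr
    w = np.where(total > 0, fzl / np.maximum(total, 1e-9), 0.5)
    ml = (w * np.nan_to_num(trial.forces["left"]["cop"][:, 1])
          + (1 - w) * np.nan_to_num(trial.forces["right"]["cop"][:, 1]))
    ml[total == 0] = np.nan
    idx = np.flatnonzero(np.isfinite(ml))
    ml = np.interp(np.arange(ml.size), idx, ml[idx])
    ev = detect_gait_events_from_cop(trial.force_t, ml)
    # interior events only: the sweep bounding the record-final stance has no
    # destination foot, so the trace ends without it (edge cycles drop out)
    for side in ("left", "right"):
        for det, tru in ((ev.heel_strikes[side], trial.truth.heel_strikes[side]),
                         (ev.toe_offs[side], trial.truth.toe_offs[side])):
            assert all(np.min(np.abs(det - x)) <= 0.010 for x in tru[1:-1])


def test_midswing_is_half_of_step():
    ev = _periodic_events(5, stride=1.0, swing=0.4)
    win = segment_strides(ev, select_n=5)
    df = win.table
    np.testing.assert_allclose(df["midswing_t"],
                               0.5 * (df["toe_off_t"] + df["heel_strike_t"]))
    # toe-off .. heel strike spans 0.4 of the 1.0 s stride
    np.testing.assert_allclose(df["heel_strike_t"] - df["toe_off_t"], 0.4)
    np.testing.assert_allclose(df["stride_time"], 1.0)


def test_final_200_of_220_strides_selected():
    ev = _periodic_events(220)
    win = segment_strides(ev, select_n=200)
    assert not win.truncated
    assert len(win.table) == 400
    # steps are contiguous and final: the last heel strike equals the last
    # complete stride boundary and strides span exactly 200 stride times
    hs = win.table["heel_strike_t"].to_numpy()
    assert hs[-1] - hs[0] == pytest.approx(200.0 - 0.5)


def test_fewer_strides_than_requested_flags_truncation():
    ev = _periodic_events(20)
    win = segment_strides(ev, select_n=200)
    assert win.truncated
    assert len(win.table) > 0


def test_trailing_toe_off_dropped():
    ev = _periodic_events(5)
    ev.toe_offs["right"] = np.append(ev.toe_offs["right"],
                                     ev.heel_strikes["right"][-1] + 0.6)
    win = segment_strides(ev, select_n=5)
    assert win.table["toe_off_t"].max() < ev.toe_offs["right"][-1]


def test_segmentation_idempotent_and_counts_conserved():
    ev = _periodic_events(30)
    a = segment_strides(ev, select_n=30).table
    b = segment_strides(ev, select_n=30).table
    pd.testing.assert_frame_equal(a, b)
    # count conservation: every surviving step is a (toe-off, heel-strike) pair
    for side in ("left", "right"):
        sub = a[a["side"] == side]
        assert len(sub) == len(sub["toe_off_t"].unique())
        assert (sub["heel_strike_t"] > sub["toe_off_t"]).all()


def test_empty_events_give_empty_windows():
    ev = GaitEvents({"left": np.array([]), "right": np.array([])},
                    {"left": np.array([]), "right": np.array([])})
    win = segment_strides(ev)
    assert len(win.table) == 0


def test_event_validation_catches_unmatched_toe_off():
    ev = GaitEvents({"left": np.array([1.0]), "right": np.array([0.5])},
                    {"left": np.array([0.6, 1.6]), "right": np.array([1.1])})
    ev.validate()  # well-formed
    bad = GaitEvents({"left": np.array([]), "right": np.array([])},
                     {"left": np.array([0.5, 1.5]), "right": np.array([])})
    with pytest.raises(ValueError):
        bad.validate()
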