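"""End-to-end orchestration: trial -> step table -> model fits -> hypotheses.

``analyze_trial`` runs one trial through event detection, CoM/foot-frame
kinematics, EMG processing, step-table assembly and the three regression
models. ``run_pipeline`` maps it over a cohort, assembles the per-cell fit
table, and runs the group-level hypothesis suite. Outputs are deterministic
for a fixed configuration and inputs (no timestamps inside output files).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import MUSCLES, RunConfig, default_anthropometry
from .emg import emg_scalar, process_emg, stride_normalize
from .events import StepWindows, detect_gait_events, segment_strides
from .exceptions import InsufficientDataError
from .io import TrialBundle, bundle_from_trial, load_bundle
from .kinematics import (
    StepTable,
    compute_com,
    compute_cop_shift,
    compute_fp_and_predictors,
)
from .models import (
    AnkleStrategyFit,
    FootPlacementFit,
    MuscleFit,
    fit_ankle_strategy_model,
    fit_foot_placement_model,
    fit_muscle_model,
)
from .bayes import hypothesis_suite
from .synth import SynthTrial

logger = logging.getLogger("gaitstab")

TrialLike = Union[TrialBundle, SynthTrial]


@dataclass
class TrialResult:
    step_table: StepTable
    windows: StepWindows
    fit1: FootPlacementFit
    fit2: Dict[int, AnkleStrategyFit]     # keyed by i_used
    fit3: Optional[MuscleFit]
    summary: dict                         # one wide row for the fit table


def _as_bundle(trial: TrialLike, **meta) -> TrialBundle:
    if isinstance(trial, SynthTrial):
        return bundle_from_trial(trial, **meta)
    if meta:
        trial.metadata.update(meta)
    return trial


def _ankle_ml(bundle: TrialBundle, side: str) -> np.ndarray:
    med = bundle.landmarks[f"{side}_medial_malleolus"][:, 1]
    lat = bundle.landmarks[f"{side}_lateral_malleolus"][:, 1]
    return 0.5 * (med + lat)


def _estimate_body_weight(bundle: TrialBundle) -> float:
    total = sum(bundle.forces[s]["fz"] for s in bundle.forces)
    loaded = total[total > 0]
    if loaded.size == 0:
        return 0.0
    return float(np.median(loaded))


def build_step_table(
    bundle: TrialBundle,
    windows: StepWindows,
    config: RunConfig,
    anthropometry: Optional[pd.DataFrame] = None,
) -> StepTable:
    """Assemble the per-step table every model consumes."""
    wdf = windows.table
    if len(wdf) < 3:
        raise InsufficientDataError("fewer than 3 complete steps")
    if anthropometry is None:
        anthropometry = default_anthropometry()

    com = compute_com(bundle.segments, anthropometry, bundle.kin_t)
    foot_ml = {s: _ankle_ml(bundle, s) for s in ("left", "right")}
    fp, com_pos, com_vel, fp_mean = compute_fp_and_predictors(com, foot_ml, wdf)

    # single-stance CoP shift under the placed foot, in its local frame;
    # frames are built from the landmarks at single-stance onset (the foot is
    # planted throughout, so the instant within stance is immaterial)
    t_f = bundle.force_t
    kin_t = bundle.kin_t
    n_steps = len(wdf)
    sides_arr = wdf["side"].to_numpy()
    ss_start = wdf["ss_start_t"].to_numpy()
    ss_end = wdf["ss_end_t"].to_numpy()
    lat_axis = np.empty((n_steps, 3))
    origin = np.empty((n_steps, 3))
    for side in ("left", "right"):
        rows = np.flatnonzero(sides_arr == side)
        if rows.size == 0:
            continue
        ts = ss_start[rows]
        pts = {
            name: np.column_stack([
                np.interp(ts, kin_t, bundle.landmarks[f"{side}_{name}"][:, i])
                for i in range(3)
            ])
            for name in ("medial_malleolus", "lateral_malleolus", "calcaneus", "toe")
        }
        ankle = 0.5 * (pts["medial_malleolus"] + pts["lateral_malleolus"])
        ml = np.cross(ankle - pts["calcaneus"], pts["toe"] - pts["calcaneus"])
        norms = np.linalg.norm(ml, axis=1, keepdims=True)
        if np.any(norms < 1e-9):
            raise InsufficientDataError("degenerate foot landmarks during stance")
        ml = ml / norms
        med_lat = pts["lateral_malleolus"] - pts["medial_malleolus"]
        flip = np.where(np.einsum("ij,ij->i", ml, med_lat) < 0, -1.0, 1.0)
        lat_axis[rows] = ml * flip[:, None]
        origin[rows] = ankle
    lo = np.searchsorted(t_f, ss_start - 1e-9)
    hi = np.searchsorted(t_f, ss_end + 1e-9)
    shifts = np.empty(n_steps)
    for j in range(n_steps):
        cop = bundle.forces[sides_arr[j]]["cop"][lo[j]:hi[j]]
        local = (cop - origin[j]) @ lat_axis[j]
        shifts[j] = compute_cop_shift(local, t_f[lo[j]:hi[j]],
                                      (ss_start[j], ss_end[j]))
    cop_mean = float(shifts.mean())
    shifts = shifts - cop_mean

    emg_scalars = None
    if bundle.emg is not None and bundle.emg_t is not None and len(bundle.emg):
        fs = 1.0 / (bundle.emg_t[1] - bundle.emg_t[0])
        emg_scalars = np.full((len(wdf), len(MUSCLES)), np.nan)
        for side in ("left", "right"):
            rows = np.flatnonzero((wdf["side"] == side).to_numpy())
            if rows.size == 0:
                continue
            strides = [
                (wdf["heel_strike_t"].iloc[r], wdf["stride_end_t"].iloc[r])
                for r in rows
            ]
            durations = np.array([b - a for a, b in strides])
            for m_i, muscle in enumerate(MUSCLES):
                env = process_emg(bundle.emg[(side, muscle)], fs,
                                  config.emg_highpass_hz, config.emg_lowpass_hz)
                norm = stride_normalize(env, bundle.emg_t, strides)
                scal = emg_scalar(norm, durations, config.early_stance_fraction)
                emg_scalars[rows, m_i] = scal - scal.mean()   # demean per side+channel

    return StepTable(
        side=wdf["side"].to_numpy(),
        stride_index=np.arange(len(wdf)),
        fp=fp,
        com_pos=com_pos,
        com_vel=com_vel,
        cop_shift=shifts,
        emg=emg_scalars,
        fp_mean=fp_mean,
        cop_shift_mean=cop_mean,
    )


def analyze_trial(
    trial: TrialLike,
    config: RunConfig = RunConfig(),
    anthropometry: Optional[pd.DataFrame] = None,
    **meta,
) -> TrialResult:
    """Run one trial end to end: events, step table, models 1-3."""
    bundle = _as_bundle(trial, **meta)
    bw = bundle.body_weight or _estimate_body_weight(bundle)
    events = detect_gait_events(
        bundle.force_t, {s: bundle.forces[s]["fz"] for s in bundle.forces},
        bw, config.force_threshold_fraction,
    )
    windows = segment_strides(events, config.select_n_strides,
                              config.early_stance_fraction)
    table = build_step_table(bundle, windows, config, anthropometry)
    fit1 = fit_foot_placement_model(table)
    fit2 = {i: fit_ankle_strategy_model(table, fit1, i_used=i, subset=config.subset)
            for i in config.i_used}
    fit3 = None
    if table.emg is not None:
        fit3 = fit_muscle_model(table)

    summary = {
        "participant": bundle.metadata.get("participant"),
        "condition": bundle.metadata.get("condition"),
        "speed": bundle.metadata.get("speed"),
        "n_steps": len(table),
        "strides_truncated": windows.truncated,
        "fp_sd_cm": float(table.fp.std()) * 100.0,
        "cop_shift_sd_cm": float(table.cop_shift.std()) * 100.0,
    }
    for i, f in fit2.items():
        summary[f"beta_error_{i}"] = f.beta_error
        summary[f"r2_2_{i}"] = f.r2
        summary[f"aev2_{i}"] = f.aev
    if fit3 is not None:
        for m_i, m in enumerate(MUSCLES):
            summary[f"beta_{m}"] = float(fit3.beta_cm[m_i])
        summary["r2_3"] = fit3.r2
        summary["aev3"] = fit3.aev
    return TrialResult(step_table=table, windows=windows, fit1=fit1,
                       fit2=fit2, fit3=fit3, summary=summary)


def run_pipeline(
    config: RunConfig,
    cohort: Mapping[Tuple[int, str, str], TrialLike],
    output_dir: Optional[Path] = None,
) -> dict:
    """Analyze every trial of a cohort and run the hypothesis suite.

    ``cohort`` maps (participant, condition, speed) to trials (bundles or
    synthetic trials). Returns a dict with the fit table, per-trial results
    and the hypothesis report; writes ``fit_table.csv``,
    ``hypothesis_report.json`` and ``run_log.json`` when an output directory
    is given.
    """
    rows = []
    results = {}
    for key in sorted(cohort):
        pid, cond, speed = key
        res = analyze_trial(cohort[key], config,
                            participant=pid, condition=cond, speed=speed)
        results[key] = res
        rows.append(res.summary)
    fit_table = pd.DataFrame(rows)

    report = None
    if len(fit_table) and fit_table["participant"].nunique() >= 3:
        try:
            report = hypothesis_suite(fit_table, rscale=config.rscale)
        except (InsufficientDataError, ValueError, KeyError) as exc:
            logger.warning("hypothesis stage skipped: %s", exc)
    else:
        logger.warning("hypothesis stage skipped: fewer than 3 participants")

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fit_table.to_csv(out / "fit_table.csv", index=False)
        if report is not None:
            with open(out / "hypothesis_report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
        cfg = asdict(config)
        cfg["i_used"] = list(cfg["i_used"])
        run_log = {
            "package_version": __version__,
            "config": cfg,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
            "n_trials": len(fit_table),
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
    return {"fit_table": fit_table, "results": results, "report": report}


def load_cohort(root: Path | str) -> Dict[Tuple[int, str, str], TrialBundle]:
    """Load every trial directory under ``root`` (fails fast on bad paths)."""
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    cohort = {}
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        b = load_bundle(d)
        key = (b.metadata.get("participant", d.name),
               b.metadata.get("condition", "steady"),
               b.metadata.get("speed", "normal"))
        cohort[key] = b
    if not cohort:
        raise FileNotFoundError(f"no trial directories under {root}")
    return cohort
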