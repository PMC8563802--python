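"""On-disk trial format: delimited text, one wide file per stream.

A trial directory holds ``kinematics.csv`` (50 samples/s), ``forces.csv``
(1000 samples/s), optionally ``emg.csv`` (2000 samples/s) and ``meta.yaml``.
Every stream file has a mandatory header, a ``t`` column in seconds and one
column per channel; missing values are empty fields; rows may arrive in any
order (they are sorted by time on read). Floats round-trip at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .config import SIDES, MUSCLES
from .exceptions import SchemaError
from .synth import SynthTrial

_LANDMARK_NAMES = [
    f"{side}_{name}" for side in SIDES
    for name in ("medial_malleolus", "lateral_malleolus", "calcaneus", "toe")
]


@dataclass
class TrialBundle:
    """One trial's metadata plus in-memory streams."""

    metadata: dict                      # participant, condition, speed, body_mass, ...
    kin_t: np.ndarray
    landmarks: Dict[str, np.ndarray]                     # name -> (N, 3)
    segments: Dict[str, Tuple[np.ndarray, np.ndarray]]   # name -> (prox, dist)
    force_t: np.ndarray
    forces: Dict[str, Dict[str, np.ndarray]]             # side -> {fz, cop}
    emg_t: Optional[np.ndarray] = None
    emg: Optional[Dict[Tuple[str, str], np.ndarray]] = None

    @property
    def body_weight(self) -> Optional[float]:
        mass = self.metadata.get("body_mass")
        return None if mass is None else float(mass) * 9.81


def bundle_from_trial(trial: SynthTrial, **metadata) -> TrialBundle:
    """Wrap a synthetic trial so it enters the pipeline like recorded data."""
    meta = {
        "participant": 0,
        "condition": trial.params.condition,
        "speed": trial.params.speed,
        "body_mass": trial.params.body_mass,
        "leg_length": trial.params.leg_length,
    }
    meta.update(metadata)
    return TrialBundle(
        metadata=meta,
        kin_t=trial.kin_t,
        landmarks=trial.landmarks,
        segments=trial.segments,
        force_t=trial.force_t,
        forces=trial.forces,
        emg_t=trial.emg_t,
        emg=trial.emg,
    )


def read_timeseries(path: Path | str, required: Tuple[str, ...] = ()) -> pd.DataFrame:
    """Read one stream file; sort by time; validate schema and uniform rate."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns:
        raise SchemaError(f"{path}: missing 't' column")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df.sort_values("t", kind="mergesort").reset_index(drop=True)
    dt = np.diff(df["t"].to_numpy())
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise SchemaError(f"{path}: non-uniform sampling (rate inference failed)")
    return df


def save_bundle(bundle: TrialBundle, directory: Path | str) -> Path:
    """Write a trial bundle as the delimited-text trial format."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    kin = {"t": bundle.kin_t}
    for name, arr in bundle.landmarks.items():
        for i, ax in enumerate("xyz"):
            kin[f"{name}_{ax}"] = arr[:, i]
    for name, (prox, dist) in bundle.segments.items():
        for end, arr in (("prox", prox), ("dist", dist)):
            for i, ax in enumerate("xyz"):
                kin[f"{name}_{end}_{ax}"] = arr[:, i]
    pd.DataFrame(kin).to_csv(d / "kinematics.csv", index=False, float_format="%.17g")

    frc = {"t": bundle.force_t}
    for side in bundle.forces:
        frc[f"{side}_fz"] = bundle.forces[side]["fz"]
        for i, ax in enumerate("xyz"):
            frc[f"{side}_cop_{ax}"] = bundle.forces[side]["cop"][:, i]
    pd.DataFrame(frc).to_csv(d / "forces.csv", index=False, float_format="%.17g")

    if bundle.emg is not None:
        emg = {"t": bundle.emg_t}
        for (side, muscle), arr in bundle.emg.items():
            emg[f"{side}_{muscle}"] = arr
        pd.DataFrame(emg).to_csv(d / "emg.csv", index=False, float_format="%.17g")

    with open(d / "meta.yaml", "w") as fh:
        yaml.safe_dump(bundle.metadata, fh, sort_keys=True)
    return d


def load_bundle(directory: Path | str) -> TrialBundle:
    """Read a trial directory back into a bundle (inverse of save_bundle)."""
    d = Path(directory)
    if not d.exists():
        raise FileNotFoundError(d)
    meta_path = d / "meta.yaml"
    metadata = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = yaml.safe_load(fh) or {}

    kin = read_timeseries(d / "kinematics.csv")
    landmarks = {}
    for name in _LANDMARK_NAMES:
        cols = [f"{name}_{ax}" for ax in "xyz"]
        if not all(c in kin.columns for c in cols):
            raise SchemaError(f"kinematics.csv: missing landmark columns for {name}")
        landmarks[name] = kin[cols].to_numpy()
    segments = {}
    seg_names = sorted({
        c[: -len("_prox_x")] for c in kin.columns if c.endswith("_prox_x")
    })
    for name in seg_names:
        prox = kin[[f"{name}_prox_{ax}" for ax in "xyz"]].to_numpy()
        dist = kin[[f"{name}_dist_{ax}" for ax in "xyz"]].to_numpy()
        segments[name] = (prox, dist)

    frc = read_timeseries(d / "forces.csv",
                          required=tuple(f"{s}_fz" for s in SIDES))
    forces = {}
    for side in SIDES:
        forces[side] = {
            "fz": frc[f"{side}_fz"].to_numpy(),
            "cop": frc[[f"{side}_cop_{ax}" for ax in "xyz"]].to_numpy(),
        }

    emg_t = None
    emg = None
    emg_path = d / "emg.csv"
    if emg_path.exists():
        edf = read_timeseries(emg_path)
        emg_t = edf["t"].to_numpy()
        emg = {}
        for side in SIDES:
            for muscle in MUSCLES:
                col = f"{side}_{muscle}"
                if col in edf.columns:
                    emg[(side, muscle)] = edf[col].to_numpy()

    return TrialBundle(
        metadata=metadata,
        kin_t=kin["t"].to_numpy(),
        landmarks=landmarks,
        segments=segments,
        force_t=frc["t"].to_numpy(),
        forces=forces,
        emg_t=emg_t,
        emg=emg,
    )
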