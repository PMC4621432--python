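"""File formats, experiment configuration and run manifests.

One CSV schema per data kind, regardless of whether the data came from the
simulator or from video tracking, so either source can feed the analysis:

- tracks:  track_id, frame, t_s, x_cm, y_cm, sex
- eggs:    egg_id, x_cm, y_cm, region
- spikes:  trial_id, spike_time_s  (+ JSON trial metadata)
- EAG:     t_s, mV                 (+ JSON metadata: fs, onset, windows)

Floating-point output is written with 9 significant digits so re-runs with
the same seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import ArenaGeometry, Quadrant
from .synthetic import Phase, SimulationConfig
from .tracking import TrackSet

log = logging.getLogger("quadfly")

FLOAT_FORMAT = "%.9g"

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_cm", "y_cm", "sex"]
EGG_COLUMNS = ["egg_id", "x_cm", "y_cm", "region"]
SPIKE_COLUMNS = ["trial_id", "spike_time_s"]


def write_tracks_csv(ts: TrackSet, path: str | Path) -> Path:
    path = Path(path)
    ts.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_tracks_csv(
    path: str | Path, frame_rate: float, arena: ArenaGeometry
) -> TrackSet:
    df = pd.read_csv(path)
    missing = [c for c in ("track_id", "frame", "x_cm", "y_cm") if c not in df.columns]
    if missing:
        raise ValueError(f"track file {path} is missing required columns: {missing}")
    return TrackSet.from_dataframe(df, frame_rate=frame_rate, arena=arena)


def write_eggs_csv(eggs: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    eggs.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_eggs_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("x_cm", "y_cm") if c not in df.columns]
    if missing:
        raise ValueError(f"egg file {path} is missing required columns: {missing}")
    return df


def write_spikes_csv(
    trains, path: str | Path, meta_path: str | Path | None = None
) -> Path:
    """Write spike trains as (trial_id, spike_time_s) rows plus metadata."""
    path = Path(path)
    rows = []
    meta = {"trials": []}
    for i, tr in enumerate(trains):
        for t in tr.spike_times:
            rows.append((i, float(t)))
        meta["trials"].append(
            {
                "trial_id": i,
                "stim_onset_s": tr.stim_onset,
                "trial_duration_s": tr.trial_duration,
                "label": tr.label,
            }
        )
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(meta, indent=1))
    return path


def read_spikes_csv(path: str | Path, meta_path: str | Path):
    """Read spike trains back: list of SpikeTrain in trial order."""
    from .ephys import SpikeTrain

    df = pd.read_csv(path)
    meta = json.loads(Path(meta_path).read_text())
    trains = []
    for trial in meta["trials"]:
        tid = trial["trial_id"]
        times = np.sort(
            df.loc[df["trial_id"] == tid, "spike_time_s"].to_numpy(float)
        )
        trains.append(
            SpikeTrain(
                spike_times=times,
                stim_onset=trial["stim_onset_s"],
                trial_duration=trial["trial_duration_s"],
                label=trial.get("label", "none"),
            )
        )
    return trains


def write_eag_csv(t: np.ndarray, v: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": t, "mV": v}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )
    return path


def read_eag_csv(path: str | Path):
    df = pd.read_csv(path)
    return df["t_s"].to_numpy(float), df["mV"].to_numpy(float)


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one end-to-end run needs, loadable from YAML/JSON."""

    arena: ArenaGeometry
    simulation: SimulationConfig
    odor_quadrant: Quadrant = Quadrant.Q1
    window: tuple[float, float] | None = None
    rotation: int = 0
    field_enabled: bool = False
    evaporation_rate: float = 1.0 / 900.0
    deposit_rate: float = 1.0
    temperature_factor: float = 1.0
    tracking: dict = dc_field(default_factory=dict)
    raw: dict = dc_field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        try:
            arena_d = d.get("arena", {})
            arena = ArenaGeometry(
                side_length=arena_d.get("side_length_cm", 19.5),
                px_per_cm=arena_d.get("px_per_cm", 10.0),
                rotation=arena_d.get("rotation_deg", 0),
                mask_polygon=tuple(tuple(v) for v in arena_d["mask_polygon"])
                if arena_d.get("mask_polygon")
                else None,
            )
            sim_d = d.get("simulation", {})
            phases = tuple(
                Phase(
                    name=p["name"],
                    duration=float(p["duration_s"]),
                    odor_quadrant=Quadrant(p["odor_quadrant"])
                    if p.get("odor_quadrant")
                    else None,
                    odor_is_food=bool(p.get("odor_is_food", False)),
                )
                for p in sim_d.get("phases", [{"name": "pre", "duration_s": 300.0}])
            )
            sim = SimulationConfig(
                n_flies=int(sim_d.get("n_flies", 45)),
                frame_rate=float(sim_d.get("frame_rate", 30.0)),
                phases=phases,
                sex_of_agents=tuple(sim_d["sexes"]) if sim_d.get("sexes") else None,
                step_speed_mean=float(sim_d.get("step_speed_mean", 1.5)),
                turn_persistence=float(sim_d.get("turn_persistence", 0.7)),
                bias_strength=float(sim_d.get("bias_strength", 2.0)),
                seed=int(sim_d.get("seed", 0)),
            )
            analysis = d.get("analysis", {})
            fld = d.get("field", {})
            window = analysis.get("window_s")
            return cls(
                arena=arena,
                simulation=sim,
                odor_quadrant=Quadrant(analysis.get("odor_quadrant", "Q1")),
                window=tuple(float(w) for w in window) if window else None,
                rotation=int(analysis.get("rotation_deg", 0)),
                field_enabled=bool(fld.get("enabled", False)),
                evaporation_rate=float(fld.get("evaporation_rate", 1.0 / 900.0)),
                deposit_rate=float(fld.get("deposit_rate", 1.0)),
                temperature_factor=float(fld.get("temperature_factor", 1.0)),
                tracking=dict(d.get("tracking", {})),
                raw=d,
            )
        except (KeyError, TypeError, ValueError) as e:
            raise ValueError(f"invalid experiment config: {e}") from e

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        d = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        if not isinstance(d, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(
    path: str | Path,
    config_dict: dict,
    seed: int | None,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> Path:
    """Record config hash, software version, seed, timestamps and file
    checksums so a run can be verified as reproduced."""
    manifest = {
        "software": "quadfly",
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config_hash": config_hash(config_dict),
        "config": config_dict,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
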