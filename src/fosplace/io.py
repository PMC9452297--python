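"""Session-bundle I/O.

A session bundle is a directory with HDF5 arrays (traces, position, speed,
trial ids), CSV tables (trials, licks, rewards, induction, alignment) and a
YAML config echo.  Conventions: all coordinates 0-based, intervals
half-open, positions in cm, bins indexed 0..n_bins-1, trace matrices are
(cells, frames) row-major.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import SessionTimeseries
from .synthetic import SessionData, SimConfig

__all__ = [
    "Bundle",
    "write_bundle",
    "read_bundle",
    "write_multisession",
    "read_image",
    "write_image",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-plane TIFF (e.g. a registered mean GFP image)."""
    import tifffile

    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane image, got shape {img.shape}")
    return np.asarray(img, dtype=float)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a 2-D array as a single-plane float32 TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(img, dtype=np.float32))


@dataclass
class Bundle:
    session: SessionTimeseries
    dff: np.ndarray
    induction: pd.DataFrame | None
    global_ids: np.ndarray
    config: dict


def _session_config_dict(config: SimConfig) -> dict:
    return dict(
        frame_rate_hz=float(config.frame_rate_hz),
        track_length_cm=float(config.track_length_cm),
        reward_zone=[float(v) for v in config.reward_zone],
        n_bins=int(config.n_bins),
    )


def write_bundle(path: str | Path, data: SessionData, config: SimConfig) -> Path:
    """Write one session bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    present = (
        data.present if data.present is not None else np.ones(data.dff.shape[0], bool)
    )
    gids = np.flatnonzero(present)
    s = data.session
    with h5py.File(path / "traces.h5", "w") as f:
        f.create_dataset("dff", data=data.dff[present], compression="gzip")
        f.create_dataset("global_id", data=gids)
    with h5py.File(path / "behavior.h5", "w") as f:
        f.create_dataset("position", data=s.position)
        f.create_dataset("speed", data=s.speed)
        f.create_dataset("trial_id", data=s.trial_id)
    s.trials.to_csv(path / "trials.csv", index=False)
    s.licks.to_csv(path / "licks.csv", index=False)
    s.rewards.to_csv(path / "rewards.csv", index=False)
    if data.induction is not None:
        pd.DataFrame(
            dict(
                cell_id=np.arange(gids.size),
                global_id=gids,
                fold_induction=data.induction[present],
            )
        ).to_csv(path / "induction.csv", index=False)
    with open(path / "config.yaml", "w") as f:
        yaml.safe_dump(_session_config_dict(config), f)
    return path


def read_bundle(path: str | Path) -> Bundle:
    """Read a session bundle, validating the shared frame count."""
    path = Path(path)
    with open(path / "config.yaml") as f:
        cfg = yaml.safe_load(f)
    with h5py.File(path / "traces.h5") as f:
        dff = f["dff"][:]
        gids = f["global_id"][:] if "global_id" in f else np.arange(dff.shape[0])
    with h5py.File(path / "behavior.h5") as f:
        position = f["position"][:]
        speed = f["speed"][:]
        trial_id = f["trial_id"][:]
    if not (position.size == speed.size == trial_id.size == dff.shape[1]):
        raise ValueError(f"{path}: frame counts disagree across arrays")
    trials = pd.read_csv(path / "trials.csv")
    licks = pd.read_csv(path / "licks.csv")
    rewards = pd.read_csv(path / "rewards.csv")
    induction = None
    if (path / "induction.csv").exists():
        induction = pd.read_csv(path / "induction.csv")
    session = SessionTimeseries(
        frame_rate=cfg["frame_rate_hz"],
        track_length=cfg["track_length_cm"],
        reward_zone=tuple(cfg["reward_zone"]),
        position=position,
        speed=speed,
        trial_id=trial_id,
        licks=licks,
        rewards=rewards,
        trials=trials,
    )
    return Bundle(session=session, dff=dff, induction=induction, global_ids=gids, config=cfg)


def write_multisession(
    path: str | Path,
    sessions: list[SessionData],
    alignment: pd.DataFrame,
    config: SimConfig,
) -> list[Path]:
    """Write aligned bundles as session00, session01, ... plus alignment.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dirs = [
        write_bundle(path / f"session{i:02d}", data, config)
        for i, data in enumerate(sessions)
    ]
    alignment.to_csv(path / "alignment.csv", index=False)
    return dirs
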