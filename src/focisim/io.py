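"""CSV track tables, YAML configuration, run manifests and fixture suites.

The trajectory table is a plain CSV with header
``track_id,frame,t_s,x_um,y_um[,z_um][,bound]``: comma separator, decimal
point, UTF-8, 0-based contiguous frames within a track.  Files with a
``z_um`` column load as 3D :class:`~focisim.trajectory.Trajectory` objects,
otherwise as 2D :class:`~focisim.trajectory.ObservedTrack`; a frame gap
splits a track into separate observed tracks.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import Geometry, LPMParams, PBMParams, SimulationConfig
from .trajectory import ObservedTrack, Trajectory

__all__ = [
    "read_tracks",
    "write_tracks",
    "load_config",
    "lpm_params_from_config",
    "pbm_params_from_config",
    "sim_config_from_config",
    "RunManifest",
    "generate_fixtures",
    "FIXTURE_SUITES",
]

_REQUIRED_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]
_POSITION_LIMIT_UM = 10.0


def write_tracks(
    path: Union[str, Path],
    tracks: Union[Trajectory, ObservedTrack, Sequence[Union[Trajectory, ObservedTrack]]],
) -> None:
    """Write tracks as a trajectory-table CSV (9 significant digits)."""
    if isinstance(tracks, (Trajectory, ObservedTrack)):
        tracks = [tracks]
    frames = []
    for k, tr in enumerate(tracks):
        if isinstance(tr, Trajectory):
            frames.append(tr.to_frame(track_id=str(k)))
        else:
            frames.append(
                pd.DataFrame(
                    {
                        "track_id": str(k),
                        "frame": np.arange(len(tr), dtype=int),
                        "t_s": tr.t,
                        "x_um": tr.xy[:, 0],
                        "y_um": tr.xy[:, 1],
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.9g")


def _split_contiguous(sub: pd.DataFrame) -> List[pd.DataFrame]:
    frames = sub["frame"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        row = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 1
        raise ValueError(
            f"track {sub['track_id'].iloc[0]!r}: frames not strictly increasing "
            f"at row {sub.index[row]}"
        )
    breaks = np.flatnonzero(np.diff(frames) > 1)
    return [sub.iloc[chunk] for chunk in np.split(np.arange(len(sub)), breaks + 1)]


def read_tracks(path: Union[str, Path]) -> List[Union[Trajectory, ObservedTrack]]:
    """Read a trajectory-table CSV.

    Returns 3D trajectories if a ``z_um`` column is present, otherwise 2D
    observed tracks.  Frame gaps split tracks; malformed input raises with
    the offending column or row named.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (track_id, frame) key at row {int(dup.idxmax())}")
    pos_cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in df.columns else [])
    bad = df[pos_cols].abs().to_numpy().max(axis=1) > _POSITION_LIMIT_UM
    if bad.any():
        raise ValueError(
            f"{path}: position outside ±{_POSITION_LIMIT_UM} μm at row "
            f"{int(np.flatnonzero(bad)[0])} (units must be μm)"
        )
    three_d = "z_um" in df.columns
    out: List[Union[Trajectory, ObservedTrack]] = []
    for tid, sub in df.groupby("track_id", sort=False):
        for piece in _split_contiguous(sub):
            t = piece["t_s"].to_numpy(dtype=float)
            if three_d:
                pos = piece[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
                bound = (
                    piece["bound"].to_numpy(dtype=int) if "bound" in piece.columns else None
                )
                out.append(Trajectory(t=t, pos=pos, bound=bound, params=None, seed=-1))
            else:
                xy = piece[["x_um", "y_um"]].to_numpy(dtype=float)
                out.append(ObservedTrack(t=t, xy=xy, source_id=str(tid)))
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG: Dict[str, float] = {
    # geometry (both models)
    "r_f": 0.1,
    "r_n": 0.5,
    "Dn": 1.0,
    # droplet model
    "D0": 0.05,
    "A": 5.0,
    "b": 1000.0,
    # binding-site model
    "rho": 4.8e4,
    "Db": 0.005,
    "r_b": 0.01,
    "kappa": 100.0,
    "k_off": 500.0,
    "crowder_count": 0,
    # measurement
    "sigma_noise": 0.03,
    "dt_obs": 0.02,
    "z_slab": 0.15,
    # integration
    "dt": 1e-6,
    "n_steps": 1_000_000,
    "seed": 0,
    "record_every": 1,
}


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> Dict[str, float]:
    """Load a flat YAML config, fill defaults, apply keyword overrides."""
    cfg = dict(_DEFAULT_CONFIG)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg.update(user)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def lpm_params_from_config(cfg: Dict[str, float]) -> LPMParams:
    return LPMParams(
        geometry=Geometry(r_f=cfg["r_f"], r_n=cfg["r_n"]),
        D0=cfg["D0"],
        Dn=cfg["Dn"],
        A=cfg["A"],
        b=cfg["b"],
    )


def pbm_params_from_config(cfg: Dict[str, float]) -> PBMParams:
    return PBMParams(
        geometry=Geometry(r_f=cfg["r_f"], r_n=cfg["r_n"]),
        Dn=cfg["Dn"],
        Db=cfg["Db"],
        rho=cfg["rho"],
        r_b=cfg["r_b"],
        kappa=cfg["kappa"],
        k_off=cfg["k_off"],
        crowder_count=int(cfg.get("crowder_count", 0)),
    )


def sim_config_from_config(cfg: Dict[str, float]) -> SimulationConfig:
    return SimulationConfig(
        dt=cfg["dt"],
        n_steps=int(cfg["n_steps"]),
        seed=int(cfg["seed"]),
        record_every=int(cfg["record_every"]),
    )


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    parameters: Dict
    seed: int
    version: str
    created: str
    outputs: Dict[str, str]

    @classmethod
    def create(
        cls, command: str, parameters: Dict, seed: int, outputs: Sequence[Union[str, Path]]
    ) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            parameters=parameters,
            seed=seed,
            version=__version__,
            created=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            outputs={str(p): _sha256(Path(p)) for p in outputs},
        )

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Fixture suites
# ---------------------------------------------------------------------------

FIXTURE_SUITES = (
    "lpm-default",
    "pbm-fast-exchange",
    "pbm-slow-exchange",
    "free-diffusion",
    "crowded",
)


def generate_fixtures(suite_name: str, seed: int, out_dir: Union[str, Path]) -> List[Path]:
    """Write a small deterministic CSV fixture for a named scenario.

    Each suite runs a short simulation at typical parameters (seconds of
    wall time) and writes the raw 3D trajectory plus observed 2D tracks.
    The same seed always produces byte-identical CSVs.
    """
    from .lpm import simulate_lpm
    from .observables import apply_measurement_model
    from .pbm import simulate_pbm

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(dt=1e-6, n_steps=2_000_000, seed=seed, record_every=200)
    if suite_name == "lpm-default":
        traj = simulate_lpm(lpm_params_from_config(load_config()), cfg)
    elif suite_name == "pbm-fast-exchange":
        traj = simulate_pbm(pbm_params_from_config(load_config(k_off=2000.0)), cfg)
    elif suite_name == "pbm-slow-exchange":
        traj = simulate_pbm(pbm_params_from_config(load_config(k_off=10.0)), cfg)
    elif suite_name == "free-diffusion":
        traj = simulate_lpm(
            lpm_params_from_config(load_config(A=0.0, D0=1.0)), cfg, start="uniform"
        )
    elif suite_name == "crowded":
        traj = simulate_pbm(pbm_params_from_config(load_config(crowder_count=100)), cfg)
    else:
        raise ValueError(f"unknown fixture suite {suite_name!r}; choose from {FIXTURE_SUITES}")
    paths = []
    traj_path = out / f"{suite_name}-traj.csv"
    write_tracks(traj_path, traj)
    paths.append(traj_path)
    obs = apply_measurement_model(traj, sigma=0.03, dt_obs=0.02, z_slab=0.15, seed=seed)
    if obs:
        obs_path = out / f"{suite_name}-observed.csv"
        write_tracks(obs_path, obs)
        paths.append(obs_path)
    return paths
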