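"""In-memory containers for simulated and observed tracks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Optional

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Time-stamped 3D positions of one tracer.

    ``bound`` is present only for binding-site (PBM) simulations, where it is
    the ground-truth per-frame bound flag.  Times have constant spacing
    ``dt · record_every`` of the generating configuration.
    """

    t: np.ndarray
    pos: np.ndarray
    bound: Optional[np.ndarray]
    params: Any
    seed: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ValueError("pos must have shape (n, 3)")
        if self.t.shape[0] != self.pos.shape[0]:
            raise ValueError("t and pos must have equal length")
        if self.bound is not None:
            self.bound = np.asarray(self.bound)
            if self.bound.shape[0] != self.t.shape[0]:
                raise ValueError("bound flag must have one entry per frame")

    @property
    def dt(self) -> float:
        """Recording interval (s)."""
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def r(self) -> np.ndarray:
        """Radial distance to the focus centre (the origin) per frame."""
        return np.linalg.norm(self.pos, axis=1)

    def to_frame(self, track_id: str = "0") -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "track_id": track_id,
                "frame": np.arange(len(self.t), dtype=int),
                "t_s": self.t,
                "x_um": self.pos[:, 0],
                "y_um": self.pos[:, 1],
                "z_um": self.pos[:, 2],
            }
        )
        if self.bound is not None:
            df["bound"] = self.bound.astype(int)
        return df


@dataclass
class ObservedTrack:
    """A 2D projected, noise-corrupted track at the observation interval.

    Gaps from z-slab exits split a trajectory into several observed tracks;
    ``source_id`` keeps the provenance link.
    """

    t: np.ndarray
    xy: np.ndarray
    source_id: str = "0"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if len(self.t) != len(self.xy):
            raise ValueError("t and xy must have equal length")
        if len(self.t) > 1:
            dts = np.diff(self.t)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
                raise ValueError("observed tracks must have a constant frame interval")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def __len__(self) -> int:
        return len(self.t)
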