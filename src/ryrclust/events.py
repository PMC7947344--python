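"""Localization event tables and the blinking-acquisition simulator.

An :class:`EventTable` is the canonical localization-microscopy input: one
row per detected single-molecule event with position (nm), frame index and
photon weight.  Tables can be simulated from a ground-truth scene or read
from CSV / HDF5 written by localization software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .config import SimulationConfig
from .scene import GroundTruthScene

__all__ = ["EventTable", "simulate_events"]

_COLUMNS = ["x_nm", "y_nm", "frame", "weight"]


@dataclass
class EventTable:
    """Rows of (x_nm, y_nm, frame, weight) plus field metadata."""

    data: pd.DataFrame
    field_size: tuple[float, float]
    n_frames: int
    source: str = "simulated"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        self.data = self.data[_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        if len(self.data) == 0:
            return
        x, y = self.data["x_nm"].to_numpy(), self.data["y_nm"].to_numpy()
        w, h = self.field_size
        bad = (x < 0) | (x > w) | (y < 0) | (y > h)
        if bad.any():
            rows = np.flatnonzero(bad)[:10]
            raise ValueError(
                f"{int(bad.sum())} events outside field bounds "
                f"{self.field_size} (first offending rows: {rows.tolist()})")
        f = self.data["frame"].to_numpy()
        if ((f < 0) | (f >= self.n_frames)).any():
            raise ValueError("frame indices outside [0, n_frames)")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def positions(self) -> np.ndarray:
        return self.data[["x_nm", "y_nm"]].to_numpy(float)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(float)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """CSV with a commented header carrying the field metadata."""
        path = Path(path)
        header = (f"# field_size_nm={self.field_size[0]},{self.field_size[1]}"
                  f" n_frames={self.n_frames} source={self.source}\n")
        with open(path, "w") as fh:
            fh.write(header)
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 field_size: tuple[float, float] | None = None,
                 n_frames: int | None = None) -> "EventTable":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
        meta: dict[str, Any] = {}
        skip = 0
        if first.startswith("#"):
            skip = 1
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        tab = pd.read_csv(path, skiprows=skip)
        if field_size is None:
            if "field_size_nm" not in meta:
                raise ValueError("field_size not given and not in file header")
            field_size = tuple(float(v) for v in meta["field_size_nm"].split(","))
        if n_frames is None:
            n_frames = int(meta.get("n_frames", tab["frame"].max() + 1 if len(tab) else 1))
        return cls(tab, field_size=field_size, n_frames=n_frames,
                   source=meta.get("source", "file"))

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            for col in _COLUMNS:
                fh.create_dataset(col, data=self.data[col].to_numpy())
            fh.attrs["field_size_nm"] = list(self.field_size)
            fh.attrs["n_frames"] = self.n_frames
            fh.attrs["source"] = self.source

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EventTable":
        with h5py.File(path, "r") as fh:
            tab = pd.DataFrame({col: fh[col][()] for col in _COLUMNS})
            field_size = tuple(float(v) for v in fh.attrs["field_size_nm"])
            n_frames = int(fh.attrs["n_frames"])
            source = str(fh.attrs.get("source", "file"))
        return cls(tab, field_size=field_size, n_frames=n_frames, source=source)


def simulate_events(scene: GroundTruthScene,
                    config: SimulationConfig | None = None) -> EventTable:
    """Simulate a blinking acquisition from a ground-truth scene.

    Each channel is labelled with probability ``labeling_efficiency``; each
    labelled channel emits a geometric number of blink events (mean
    ``blinks_per_label``); each event is the channel position plus isotropic
    Gaussian localization error of scale ``localization_sigma``.  Background
    events arrive as a homogeneous Poisson process at ``background_rate`` per
    µm² over the whole acquisition.  Frame indices are uniform.  Events that
    the localization error pushes outside the field are dropped (they would
    not be recorded from this field of view).

    Deterministic for a fixed (scene, config) pair: randomness derives from
    ``config.seed`` through a dedicated stream independent of the one used
    for scene construction.
    """
    if config is None:
        config = scene.config
    # child 4 of the master seed; children 0-3 belong to scene construction
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    w, h = scene.field_size
    area_um2 = w * h * 1e-6

    parts: list[np.ndarray] = []
    n = scene.n_channels
    if n and config.labeling_efficiency > 0:
        labelled = rng.random(n) < config.labeling_efficiency
        idx = np.flatnonzero(labelled)
        if idx.size:
            blinks = rng.geometric(1.0 / config.blinks_per_label, size=idx.size) \
                if config.blinks_per_label > 1 else np.ones(idx.size, dtype=np.int64)
            centres = np.repeat(scene.channel_positions[idx], blinks, axis=0)
            noise = (rng.normal(0.0, config.localization_sigma, size=centres.shape)
                     if config.localization_sigma > 0 else 0.0)
            parts.append(centres + noise)
    if config.background_rate > 0:
        n_bg = rng.poisson(config.background_rate * area_um2)
        if n_bg:
            parts.append(np.column_stack([rng.uniform(0, w, n_bg),
                                          rng.uniform(0, h, n_bg)]))
    if parts:
        pos = np.concatenate(parts)
        keep = ((pos[:, 0] >= 0) & (pos[:, 0] <= w)
                & (pos[:, 1] >= 0) & (pos[:, 1] <= h))
        pos = pos[keep]
    else:
        pos = np.zeros((0, 2))
    frames = rng.integers(0, config.n_frames, size=len(pos))
    tab = pd.DataFrame({
        "x_nm": pos[:, 0], "y_nm": pos[:, 1],
        "frame": frames, "weight": np.ones(len(pos)),
    })
    return EventTable(tab, field_size=scene.field_size,
                      n_frames=config.n_frames, source="simulated")
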