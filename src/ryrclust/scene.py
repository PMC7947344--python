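"""Ground-truth scene construction for the cluster-morphometry simulator.

A scene is a set of RyR2 channel positions organised into clusters, a
super-cluster (calcium release unit) structure induced by short inter-cluster
gaps, and a family of parallel z-disk bands to which a configurable fraction
of clusters is aligned.  Every morphometric quantity the analysis pipeline
later estimates from images is stored here as a brute-force-computed ground
truth, so recovery can be scored against known values.

Geometry conventions
--------------------
* Channel positions are centre coordinates in nm, ``x`` horizontal,
  ``y`` vertical, origin at the lower-left field corner.
* A cluster is a square-grid patch of channels at pitch =
  ``channel_footprint`` (optionally thinned by ``occupancy``), randomly
  rotated.
* The true edge-to-edge distance between two clusters is
  ``max(0, min-over-channel-pairs(centre distance) - channel_footprint)``:
  each channel is a ``footprint x footprint`` square, so subtracting one
  footprint from the centre-to-centre distance approximates the gap between
  the square outlines.
* z-disk bands are horizontal stripes ``|y - centre| <= width/2`` repeating
  at ``zdisk_spacing``; a cluster is "aligned" when its centroid lies in a
  band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .config import SimulationConfig

__all__ = ["GroundTruthScene", "PlacementError", "build_scene"]


class PlacementError(RuntimeError):
    """Raised when non-overlapping cluster placement fails after bounded retries."""


@dataclass
class GroundTruthScene:
    """True channel/cluster/super-cluster geometry plus stored true metrics."""

    channel_positions: np.ndarray  # (N, 2) nm
    channel_cluster_id: np.ndarray  # (N,) int, cluster index per channel
    cluster_supercluster_id: np.ndarray  # (C,) int, group index per cluster
    zdisk_bands: list[tuple[float, float]]  # (centre y nm, width nm)
    field_size: tuple[float, float]
    config: SimulationConfig
    true_metrics: dict[str, Any] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return int(self.channel_positions.shape[0])

    @property
    def n_clusters(self) -> int:
        if self.channel_cluster_id.size == 0:
            return 0
        return int(self.channel_cluster_id.max()) + 1

    def cluster_channels(self, i: int) -> np.ndarray:
        return self.channel_positions[self.channel_cluster_id == i]

    def cluster_centroids(self) -> np.ndarray:
        """(C, 2) centroid of each cluster's channel positions."""
        c = self.n_clusters
        out = np.zeros((c, 2))
        for i in range(c):
            out[i] = self.cluster_channels(i).mean(axis=0)
        return out

    # -- serialization -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write the scene as JSON (structure) + CSV (channel table)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "x_nm": self.channel_positions[:, 0],
            "y_nm": self.channel_positions[:, 1],
            "cluster_id": self.channel_cluster_id,
        }).to_csv(directory / "channels.csv", index=False)
        doc = {
            "field_size": list(self.field_size),
            "zdisk_bands": [list(b) for b in self.zdisk_bands],
            "cluster_supercluster_id": self.cluster_supercluster_id.tolist(),
            "true_metrics": _jsonable(self.true_metrics),
            "config": self.config.to_dict(),
        }
        (directory / "scene.json").write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "GroundTruthScene":
        directory = Path(directory)
        doc = json.loads((directory / "scene.json").read_text())
        tab = pd.read_csv(directory / "channels.csv")
        return cls(
            channel_positions=tab[["x_nm", "y_nm"]].to_numpy(float),
            channel_cluster_id=tab["cluster_id"].to_numpy(np.int64),
            cluster_supercluster_id=np.asarray(doc["cluster_supercluster_id"],
                                               dtype=np.int64),
            zdisk_bands=[tuple(b) for b in doc["zdisk_bands"]],
            field_size=tuple(doc["field_size"]),
            config=SimulationConfig.from_dict(doc["config"]),
            true_metrics=doc["true_metrics"],
        )


def _jsonable(d: dict[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


# -- patch geometry --------------------------------------------------------

def _make_patch(n: int, pitch: float, occupancy: float,
                rng: np.random.Generator) -> np.ndarray:
    """Channel offsets (n, 2) of a randomly rotated grid patch, centred at 0."""
    n_sites = max(n, int(np.ceil(n / occupancy)))
    cols = int(np.ceil(np.sqrt(n_sites)))
    rows = int(np.ceil(n_sites / cols))
    gx, gy = np.meshgrid(np.arange(cols), np.arange(rows))
    sites = np.column_stack([gx.ravel(), gy.ravel()]).astype(float) * pitch
    if n < len(sites):
        # keep the patch compact: prefer sites close to the grid centre
        centre = sites.mean(axis=0)
        order = np.argsort(((sites - centre) ** 2).sum(axis=1), kind="stable")
        keep = order[: max(n, int(round(len(sites) * occupancy)))]
        if len(keep) > n:
            keep = rng.choice(keep, size=n, replace=False)
        sites = sites[keep]
    sites -= sites.mean(axis=0)
    theta = rng.uniform(0, np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return sites @ rot.T


def _band_centres(field_h: float, spacing: float, phase: float) -> np.ndarray:
    first = phase % spacing
    return np.arange(first, field_h, spacing)


def _in_band(y: np.ndarray | float, bands: np.ndarray, width: float) -> np.ndarray:
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if bands.size == 0:
        return np.zeros(y.shape, dtype=bool)
    d = np.abs(y[:, None] - bands[None, :]).min(axis=1)
    return d <= width / 2.0


# -- placement -------------------------------------------------------------

_MAX_TRIES = 200


def _sample_centre(rng: np.random.Generator, cfg: SimulationConfig,
                   bands: np.ndarray, radius: float,
                   aligned: bool) -> tuple[float, float]:
    w, h = cfg.field_size
    for _ in range(_MAX_TRIES):
        x = rng.uniform(radius, max(radius + 1e-9, w - radius))
        if aligned and bands.size:
            band = bands[rng.integers(len(bands))]
            y = band + rng.uniform(-cfg.zdisk_width / 2, cfg.zdisk_width / 2)
        else:
            y = rng.uniform(radius, max(radius + 1e-9, h - radius))
            if bands.size and _in_band(y, bands, cfg.zdisk_width)[0]:
                continue
        if radius <= y <= h - radius:
            return x, y
    # fields thinner than a couple of band spacings: fall back to uniform y
    return (rng.uniform(radius, max(radius + 1e-9, w - radius)),
            rng.uniform(radius, max(radius + 1e-9, h - radius)))


def build_scene(config: SimulationConfig) -> GroundTruthScene:
    """Construct a ground-truth scene from a simulation configuration.

    Cluster count is fixed at ``round(cluster_density * field area)``.  A
    fraction ``satellite_fraction`` of clusters is placed as satellites with
    an edge gap to a randomly chosen parent drawn uniformly from
    ``[min_cluster_gap, supercluster_gap - 10 nm]``, inducing the
    super-cluster structure; the rest are placed independently (with the
    configured fraction centred on z-disk bands) subject to a minimum edge
    gap of ``min_cluster_gap`` to every other cluster.

    Raises
    ------
    PlacementError
        If non-overlapping placement fails after bounded retries (density
        too high for the field).
    """
    # hierarchical seeding: children 0-3 drive scene construction; child 4 is
    # reserved for the event simulator so scenes and acquisitions draw from
    # independent streams of the same master seed
    children = np.random.SeedSequence(config.seed).spawn(5)
    rng_sizes, rng_place, rng_patch, rng_sat = \
        (np.random.default_rng(s) for s in children[:4])

    w, h = config.field_size
    pitch = config.channel_footprint
    n_clusters = int(round(config.cluster_density * config.area_um2))
    bands = _band_centres(h, config.zdisk_spacing,
                          rng_place.uniform(0, config.zdisk_spacing))
    band_list = [(float(b), float(config.zdisk_width)) for b in bands]

    if n_clusters == 0:
        scene = GroundTruthScene(
            channel_positions=np.zeros((0, 2)),
            channel_cluster_id=np.zeros(0, dtype=np.int64),
            cluster_supercluster_id=np.zeros(0, dtype=np.int64),
            zdisk_bands=band_list, field_size=config.field_size, config=config)
        scene.true_metrics = compute_true_metrics(scene)
        return scene

    sizes = config.size_distribution.sample(rng_sizes, n_clusters)
    patches = [_make_patch(int(n), pitch, config.occupancy, rng_patch)
               for n in sizes]
    radii = np.array([np.sqrt((p ** 2).sum(axis=1)).max() + pitch / 2
                      for p in patches])

    n_sat = int(round(config.satellite_fraction * n_clusters))
    n_seed = n_clusters - n_sat
    role = rng_place.permutation(n_clusters)  # which cluster takes which role
    seed_idx, sat_idx = role[:n_seed], role[n_seed:]
    # place large patches first while space is plentiful
    seed_idx = seed_idx[np.argsort(-radii[seed_idx], kind="stable")]
    order = np.concatenate([seed_idx, sat_idx])

    placed_pts: list[np.ndarray] = []
    placed_ids: list[np.ndarray] = []
    centres = np.zeros((n_clusters, 2))
    min_gap = config.min_cluster_gap + pitch  # centre-to-centre exclusion

    def conflicts(pts: np.ndarray, exclude: int | None = None,
                  allowed_gap: float = min_gap) -> bool:
        if not placed_pts:
            return False
        tree = cKDTree(np.concatenate(placed_pts))
        ids = np.concatenate(placed_ids)
        pairs = tree.query_ball_point(pts, r=allowed_gap)
        for lst in pairs:
            for j in lst:
                if exclude is None or ids[j] != exclude:
                    return True
        return False

    # independently placed clusters
    for k in range(n_seed):
        idx = int(order[k])
        patch, radius = patches[idx], radii[idx]
        aligned = rng_place.random() < config.zdisk_aligned_fraction
        for attempt in range(_MAX_TRIES):
            cx, cy = _sample_centre(rng_place, config, bands, radius, aligned)
            pts = patch + (cx, cy)
            if not conflicts(pts):
                break
        else:
            raise PlacementError(
                f"could not place cluster {k + 1}/{n_clusters}: density "
                f"{config.cluster_density}/um2 too high for field {config.field_size}")
        placed_pts.append(pts)
        placed_ids.append(np.full(len(pts), idx, dtype=np.int64))
        centres[idx] = (cx, cy)

    # satellites: near an existing parent, designed edge gap < supercluster_gap
    parents = [int(order[k]) for k in range(n_seed)]
    for k in range(n_seed, n_clusters):
        idx = int(order[k])
        patch, radius = patches[idx], radii[idx]
        for attempt in range(_MAX_TRIES):
            parent = parents[int(rng_sat.integers(len(parents)))]
            gap = rng_sat.uniform(config.min_cluster_gap,
                                  max(config.min_cluster_gap + 1.0,
                                      config.supercluster_gap - 10.0))
            phi = rng_sat.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(phi), np.sin(phi)])
            ppts = None
            for arr, ids in zip(placed_pts, placed_ids):
                if ids[0] == parent:
                    ppts = arr
                    break
            assert ppts is not None
            # start far enough out, then slide along phi to realise the gap
            dist0 = radii[parent] + radius + gap + pitch
            centre = ppts.mean(axis=0) + direction * dist0
            pts = patch + centre
            for _ in range(4):
                d = cdist(pts, ppts).min() - pitch
                shift = d - gap
                centre = centre - direction * shift
                pts = patch + centre
            if not (np.all(pts[:, 0] >= 0) and np.all(pts[:, 0] <= w)
                    and np.all(pts[:, 1] >= 0) and np.all(pts[:, 1] <= h)):
                continue
            if conflicts(pts, exclude=parent):
                continue
            # parent proximity must respect the drawn gap, not the exclusion
            if cdist(pts, ppts).min() - pitch < config.min_cluster_gap * 0.5:
                continue
            break
        else:
            raise PlacementError(
                f"could not place satellite cluster {k + 1}/{n_clusters}")
        placed_pts.append(pts)
        placed_ids.append(np.full(len(pts), idx, dtype=np.int64))
        centres[idx] = pts.mean(axis=0)

    positions = np.concatenate(placed_pts)
    cluster_id = np.concatenate(placed_ids)
    order_idx = np.argsort(cluster_id, kind="stable")
    positions, cluster_id = positions[order_idx], cluster_id[order_idx]

    scene = GroundTruthScene(
        channel_positions=positions,
        channel_cluster_id=cluster_id,
        cluster_supercluster_id=np.zeros(n_clusters, dtype=np.int64),
        zdisk_bands=band_list,
        field_size=config.field_size,
        config=config,
    )
    edge = pairwise_edge_distances(scene)
    scene.cluster_supercluster_id = _group_by_cutoff(edge, config.supercluster_gap)
    scene.true_metrics = compute_true_metrics(scene, edge=edge)
    return scene


# -- true metrics (brute force on stored positions) ------------------------

def pairwise_edge_distances(scene: GroundTruthScene) -> np.ndarray:
    """(C, C) matrix of true edge-to-edge distances between clusters.

    Entry (i, j) is ``max(0, min channel-pair centre distance - footprint)``;
    the diagonal is +inf.  Brute force over channel pairs, blocked per
    cluster.
    """
    c = scene.n_clusters
    out = np.full((c, c), np.inf)
    if c < 2:
        return out
    pos = scene.channel_positions
    cid = scene.channel_cluster_id
    fp = scene.config.channel_footprint
    for i in range(c):
        mine = pos[cid == i]
        others = pos[cid != i]
        oid = cid[cid != i]
        d = cdist(mine, others).min(axis=0)
        # min per other cluster
        for j in range(c):
            if j == i:
                continue
            sel = oid == j
            if sel.any():
                out[i, j] = max(0.0, d[sel].min() - fp)
    return out


def _group_by_cutoff(edge: np.ndarray, cutoff: float) -> np.ndarray:
    c = edge.shape[0]
    if c == 0:
        return np.zeros(0, dtype=np.int64)
    adj = (edge <= cutoff)
    rows, cols = np.nonzero(adj)
    g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(c, c))
    _, labels = connected_components(g, directed=False)
    return labels.astype(np.int64)


def compute_true_metrics(scene: GroundTruthScene,
                         edge: np.ndarray | None = None) -> dict[str, Any]:
    """Recompute every stored true metric from positions, by brute force."""
    cfg = scene.config
    c = scene.n_clusters
    if c == 0:
        return {
            "n_clusters": 0, "n_channels": 0,
            "mean_cluster_size": float("nan"),
            "cluster_density_per_um2": 0.0,
            "nnd_nm": [], "pct_within_cutoff": float("nan"),
            "clusters_per_supercluster": float("nan"),
            "pct_zdisk_aligned": float("nan"),
        }
    if edge is None:
        edge = pairwise_edge_distances(scene)
    sizes = np.bincount(scene.channel_cluster_id, minlength=c)
    nnd = edge.min(axis=1) if c > 1 else np.full(c, np.inf)
    groups = scene.cluster_supercluster_id
    n_groups = len(np.unique(groups))
    centroids = scene.cluster_centroids()
    bands = np.array([b[0] for b in scene.zdisk_bands])
    aligned = _in_band(centroids[:, 1], bands, cfg.zdisk_width)
    return {
        "n_clusters": int(c),
        "n_channels": scene.n_channels,
        "mean_cluster_size": float(sizes.mean()),
        "cluster_density_per_um2": float(c / cfg.area_um2),
        "nnd_nm": [float(v) for v in nnd],
        "pct_within_cutoff": float(100.0 * np.mean(nnd <= cfg.supercluster_gap))
        if c > 1 else float("nan"),
        "clusters_per_supercluster": float(c / n_groups),
        "pct_zdisk_aligned": float(100.0 * aligned.mean()),
    }
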