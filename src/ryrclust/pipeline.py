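"""End-to-end analysis of a single image: render → segment → morphometry.

This is the glue used by the CLI and by recovery experiments: given an event
table (or an already rendered image) plus an optional α-actinin widefield
channel, it produces the per-image summary metrics of the study — mean
cluster size, packing density, cluster density, NND, super-cluster metrics
and z-disk alignment — together with the intermediate objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .clusters import (ClusterSet, cluster_density, nearest_neighbor_distances,
                       segment_clusters)
from .config import PipelineConfig
from .events import EventTable
from .render import RenderedImage, estimate_local_density_threshold, render_events
from .superclusters import SuperClusterSet, group_superclusters, supercluster_metrics
from .zdisk import (ZDiskMask, cluster_zdisk_alignment,
                    labeling_fraction_near_zdisk, segment_zdisks)

__all__ = ["ImageAnalysis", "analyze_image"]


@dataclass
class ImageAnalysis:
    """All products of one image's analysis."""

    image: RenderedImage
    clusters: ClusterSet
    superclusters: SuperClusterSet | None
    zdisk: ZDiskMask | None
    summary: dict[str, Any]


def analyze_image(events: EventTable | None = None,
                  image: RenderedImage | None = None,
                  actinin: RenderedImage | None = None,
                  roi: np.ndarray | None = None,
                  config: PipelineConfig | None = None) -> ImageAnalysis:
    """Run the full morphometry pipeline on one field of view.

    Provide either a localization ``events`` table (rendered at
    ``config.pixel_size``) or a pre-rendered ``image``.  The α-actinin
    channel is optional; without it the z-disk metrics are omitted.
    """
    if config is None:
        config = PipelineConfig()
    if (events is None) == (image is None):
        raise ValueError("provide exactly one of events or image")
    if image is None:
        image = render_events(events, pixel_size=config.pixel_size,
                              kernel_sigma=config.kernel_sigma)

    summary: dict[str, Any] = {"pixel_size_nm": image.pixel_size}
    threshold = estimate_local_density_threshold(
        image, policy=config.threshold_policy, value=config.threshold_value)
    cs = segment_clusters(image, threshold, min_events=config.min_events,
                          roi=roi, footprint_nm2=config.channel_footprint_nm2,
                          closing_radius_nm=config.closing_radius,
                          fill_holes=config.fill_holes,
                          mask_closing_nm=config.mask_closing_radius)
    summary["threshold"] = threshold
    summary["n_clusters"] = len(cs)
    if len(cs):
        summary["mean_cluster_size_channels"] = float(
            np.mean([c.est_channels for c in cs.clusters]))
        summary["packing_density_au"] = float(
            np.mean([c.mean_intensity for c in cs.clusters]))
        summary["cluster_density_per_um2"] = cluster_density(cs)
    else:
        summary["mean_cluster_size_channels"] = None
        summary["packing_density_au"] = None
        summary["cluster_density_per_um2"] = 0.0 \
            if cs.analysis_area_um2 else None

    nnds = nearest_neighbor_distances(cs)
    summary["mean_nnd_nm"] = float(nnds.mean()) if nnds.size else None

    sc: SuperClusterSet | None = None
    if len(cs):
        sc = group_superclusters(cs, cutoff_nm=config.supercluster_cutoff)
        scm = supercluster_metrics(sc, nnds)
        summary["pct_clusters_within_cutoff"] = scm["pct_within_cutoff"]
        summary["clusters_per_supercluster"] = scm["mean_members"]
        summary["supercluster_nnd_nm"] = scm["mean_group_nnd_nm"]

    z: ZDiskMask | None = None
    if actinin is not None:
        z = segment_zdisks(actinin)
        summary["pct_zdisk_aligned"] = cluster_zdisk_alignment(cs, z)
        summary["fraction_colocalized"] = labeling_fraction_near_zdisk(image, z, 0.0)
        summary["fraction_within_window"] = labeling_fraction_near_zdisk(
            image, z, config.zdisk_window)
    return ImageAnalysis(image=image, clusters=cs, superclusters=sc,
                         zdisk=z, summary=summary)
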