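# ryrclust

Nanoscale morphometry of cardiac ryanodine receptor (RyR2) clusters from
single-molecule localization microscopy (dSTORM), with a ground-truth
simulator for end-to-end validation.

RyR2, the sarcoplasmic-reticulum Ca²⁺-release channel, forms clusters of
~30 × 30 nm tetramers in the junctional SR membrane, aligned to the
sarcomeric z-disks.  Cluster size, packing, inter-cluster spacing and
grouping into super-clusters (calcium release units: clusters within
150 nm of each other, treated as functionally coupled) shape the cell's
propensity for arrhythmogenic spontaneous Ca²⁺ release, and are candidate
remodelling substrates in atrial fibrillation and heart failure.  This
package implements the full quantification chain used in such studies:

1. **simulate** — ground-truth scenes (channel positions on 30 nm grids,
   heavy-tailed cluster sizes with median ≈ 4 / mean ≈ 18 channels,
   4.3 clusters/µm², z-disk banding, designed sub-150 nm neighbour pairs)
   and blinking acquisitions (labelling efficiency, geometric blink
   counts, 15 nm localization error, background);
2. **render** — density-proportional 16-bit images at 5 nm/pixel
   (pixel intensity ∝ local event density; image mass = event count);
3. **cluster analysis** — threshold segmentation, per-cluster area /
   channel count (area ÷ 900 nm²) / packing density, cluster density,
   edge-to-edge nearest-neighbour distances via exact windowed distance
   transforms;
4. **super-cluster analysis** — 150 nm proximity grouping (connected
   components on exact pairwise mask distances), members per group, group
   NND;
5. **z-disk analysis** — α-actinin mask segmentation, centroid alignment,
   intensity fraction co-localized with / within 300 nm of the z-disk;
6. **clinical morphometry** — cardiomyocyte cross-sectional areas from
   label masks, Du Bois body-surface area
   (0.007184·W⁰·⁴²⁵·H⁰·⁷²⁵), indexed atrial volumes, Pearson correlation;
7. **statistics** — hierarchical aggregation (cluster → image → patient →
   group; the patient is the unit of analysis), a gated decision tree
   (Shapiro–Wilk → Kruskal–Wallis + Dunn; Brown–Forsythe–Levene → Welch
   ANOVA + Games–Howell; else one-way ANOVA + Tukey), analyst blinding,
   and study-style report tables.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

```python
import ryrclust as rc

sim = rc.SimulationConfig(field_size=(6000.0, 6000.0), seed=2,
                          labeling_efficiency=1.0)
scene = rc.build_scene(sim)                      # ground truth
events = rc.simulate_events(scene, sim)          # blinking acquisition
actinin = rc.simulate_actinin_widefield(scene)   # z-disk channel
result = rc.analyze_image(events=events, actinin=actinin,
                          config=rc.PipelineConfig())
for k in ("n_clusters", "mean_cluster_size_channels",
          "cluster_density_per_um2", "mean_nnd_nm",
          "pct_clusters_within_cutoff", "clusters_per_supercluster"):
    print(k, round(result.summary[k], 2))
print("truth:", scene.true_metrics["n_clusters"], "clusters,",
      round(scene.true_metrics["mean_cluster_size"], 2), "channels/cluster")
```

prints

```
n_clusters 144
mean_cluster_size_channels 15.69
cluster_density_per_um2 4.09
mean_nnd_nm 142.19
pct_clusters_within_cutoff 68.53
clusters_per_supercluster 1.78
truth: 155 clusters, 16.12 channels/cluster
```

i.e. on a 36 µm² field the pipeline segments 144 of 155 true clusters
(one- and two-channel clusters with too few blinks are undetectable in
principle), recovers the mean cluster size within a few percent of this
scene's truth, and reproduces the inter-cluster organisation — ~4
clusters/µm², ~140 nm nearest-neighbour distances, ~70% of clusters within
150 nm of a neighbour, ~1.8 clusters per calcium release unit.

The same chain is available from the shell:

```sh
ryrclust show-config
ryrclust simulate --out sim1 --seed 2
ryrclust analyze sim1 --out analysis --patient P1 --group non-AF
ryrclust stats analysis/image_summary.csv --out report
```

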