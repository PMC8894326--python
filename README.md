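# parcstab

Spatial stability of graph-theoretical connectome measures under random
brain-parcellation errors.

## The problem

Functional brain networks are built by parcellating the cortical surface into
regions (the network nodes), averaging BOLD time series within each parcel,
correlating parcels pairwise, and thresholding the correlation matrix.  The
parcellation step is noisy: atlas misregistration and segmentation error move
parcel borders by small amounts, and different graph measures react very
differently to such spatial errors.  `parcstab` quantifies that reaction.  It

1. **perturbs** a surface parcellation with a region-growing algorithm that
   relabels a controlled percentage *T%* of surface vertices across a fraction
   *N* of randomly selected parcels (defaults *T* = 3 %, *N* = 30 %, 100
   modified parcellations — chosen so parcel volumes fluctuate with a mean
   coefficient of variation of 10 %, the typical between-subject variability
   of a parcellation unit);
2. **rebuilds** weighted and binary functional connectomes at fixed
   correlation thresholds τ ∈ {0.1, 0.2, 0.3, 0.4} for the standard (SP) and
   every modified (MP) parcellation;
3. **recomputes** 27 graph-theoretical measures (centrality, clustering,
   core, degree, distance, modularity, physical-connectivity and similarity
   classes; 8 global, 19 local, 3 binary-only);
4. **scores** each measure's robustness with the variation factor

   local: VF(%) = (1/N)(1/P) Σₚ Σᵢ (xᵢₚᴹᴾ − xᵢₚˢᴾ)² / ((xᵢₚᴹᴾ + xᵢₚˢᴾ)/2)² · 100

   global: VF(%) = (1/N) Σᵢ (xᵢᴹᴾ − xᵢˢᴾ)² / ((xᵢᴹᴾ + xᵢˢᴾ)/2)² · 100

   (mean squared relative difference, in percent; VF = 0 means perfectly
   stable), one VF per measure and perturbation instance;
5. **tests** the effect of atlas, dataset and threshold on the per-measure
   VFs with a Pillai's-trace MANOVA and Bonferroni-corrected post hocs.

Everything runs on synthetic fixtures — icospheres with graph-Voronoi
parcellations and block-covariance BOLD-like time series — so no imaging data
are required; FreeSurfer surface/annotation files and real preprocessed
vertex time series are supported as inputs for the same pipeline.

## Worked example

```python
import numpy as np
import parcstab as ps

# surface + atlas stand-in: subdivision-4 icosphere, 64 graph-Voronoi parcels
mesh = ps.make_icosphere(4)
parc = ps.random_parcellation(mesh, 64, 0)

# 100 modified parcellations at the default operating point (T=3%, N=30%)
cfg = ps.PerturbationConfig(t_percent=3.0, n_fraction=0.30, m=100, master_seed=7)
instances = ps.generate_instances(mesh, parc, cfg)
mean_cv, _ = ps.parcel_volume_cv(parc, instances)
print(f"moved vertices per instance: "
      f"{100*min(i.moved_fraction for i in instances):.2f}-"
      f"{100*max(i.moved_fraction for i in instances):.2f}% (quota 3%)")
print(f"mean parcel-volume CV over 100 instances: {mean_cv:.2f}%")

# synthetic BOLD, one subject; VF of all 27 measures at threshold 0.2
sc = ps.SyntheticScenario(subdivisions=4, n_parcels=64, n_subjects=1,
                          n_timepoints=200, master_seed=7)
subjects, _ = ps.synthetic_timeseries(sc, parc)
ts = subjects[0]

def measures(p):
    aw, ab = ps.build_adjacencies(ts, p, thresholds=(0.2,))[0.2]
    res, _ = ps.compute_all(aw, ab, rng=np.random.default_rng(0))
    return res

sp = [measures(parc)]
mp = [[measures(inst.parcellation)] for inst in instances[:10]]
table = ps.build_stability_table(sp, mp, threshold=0.2)
print(table.groupby("measure").vf_percent.median().sort_values().round(2))
```

prints

```
moved vertices per instance: 6.95-9.21% (quota 3%)
mean parcel-volume CV over 100 instances: 19.84%
measure
get components                              0.00
k-coreness centrality                       0.67
pagerank centrality                         1.47
bonacich centrality                         2.48
global efficiency                           2.49
...
betweenness centrality                    156.83
core periphery                            193.75
assortativity                             280.28
subgraph centrality                       396.96
```

Every instance moves strictly more than the 3 % vertex quota (ring growth
overshoots it), and the VF ranking separates stable measures (component
structure, coreness, pagerank, efficiency — median VF of a few percent) from
spatially fragile ones (betweenness, subgraph centrality, assortativity —
VF well above 100 %).  A `ps.manova_pillai(table)` call then tests whether
atlas, dataset or threshold shift those VFs.

A shell-level pipeline is available too:

```sh
parcstab simulate --subdivisions 4 --parcels 64 --subjects 1 --seed 3 --out fix/
parcstab perturb  --surface fix/surface.off --annot fix/labels.txt -m 100 --seed 2 --out mp/
parcstab connect  --ts fix/timeseries_subject0.csv --surface fix/surface.off \
                  --annot fix/labels.txt --out conn/
parcstab metrics  --weighted conn/adjacency_weighted_tau0.1.csv \
                  --binary conn/adjacency_binary_tau0.1.csv --tau 0.1 --out m.csv
parcstab stats    --table table.csv --factors threshold --posthoc threshold
```

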