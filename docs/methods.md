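# Methods

## The perturbation model

A parcellation assigns every vertex of a closed triangulated cortical surface
to exactly one parcel.  A *boundary face* is a triangle whose three vertices
do not all share a label; boundary faces trace parcel borders and seed the
perturbation.  One modified parcellation (MP) instance is produced from the
standard parcellation (SP) as follows:

1. select `round(N · P)` parcels uniformly without replacement (`N` = 0.30 by
   default, minimum one parcel);
2. give each selected parcel *i* a vertex quota

   `e_i = T% · V_i · V_tot / (100 · Σ_j V_j)`,

   where `V_i` is the parcel's vertex count, `V_tot` the surface total and
   the sum runs over the selected parcels.  Quotas are proportional to parcel
   size and sum exactly to `T% · V_tot / 100` (`T` = 3 by default), so each
   selected parcel grows by the same relative amount — a parcel twice as
   large absorbs twice as many vertices;
3. process the selected parcels sequentially in random order on the evolving
   labelling.  For each: draw a small seed set of vertices from the parcel's
   boundary faces (3 by default; a single-seed variant is supported), expand
   once around the seeds, discard vertices inside the target parcel, then
   repeatedly absorb the neighbourhood of one randomly chosen member until
   the growing set exceeds `e_i`.  The final refinement granularity is one
   vertex neighbourhood, so the overshoot above `e_i` is at most one
   neighbourhood (≈ 6 vertices on a triangulated sphere);
4. relabel the grown set to the target parcel.  Donor parcels may be any
   parcels reached by the growth front; a move that would empty a donor
   aborts the instance, which is retried with a fresh sub-seed (cap 5).

Within an instance each vertex moves at most once (an accumulating forbidden
set), which guarantees the per-instance lower bound
`moved vertices / V_tot > T% / 100` — the quota-sum identity plus strict
per-parcel overshoot.  Instance `k` of an ensemble uses the counter-based
seed `(master_seed, k, retry)`, so ensembles are reproducible and instances
independent of generation order.

### Calibration

Perturbation magnitude is summarised by the mean coefficient of variation
(CV) of parcel vertex counts across instances: per parcel, the sample
standard deviation (n−1) of its count divided by its mean count, averaged
unweighted over parcels, in percent.  `calibrate_t_percent` bisects `T` until
the achieved mean CV matches a target (10 % by default, the conventional
between-subject variability of a parcellation unit); all evaluations share
one ensemble seed, under which the achieved CV is monotone in `T`, making
bisection valid.

**Resolution caveat.**  The CV floor is set by the minimum perturbation —
roughly one seed set plus one expansion per selected parcel.  On coarse
meshes where a vertex neighbourhood is a sizeable fraction of a parcel
(e.g. 2,562 vertices / 64 parcels ≈ 40 vertices per parcel), that floor
already exceeds 10 % and no `T` reaches the target.  Calibration to 10 %
therefore runs on meshes with at least ~150 vertices per parcel
(subdivision-5 icosphere for 64 parcels), the regime real cortical surfaces
(tens of thousands of vertices per hemisphere) are always in.

## Connectome construction

Per-vertex series are detrended by removing the per-column least-squares
line, averaged within parcels (unweighted), and correlated (Pearson) between
parcels.  Edges are kept where `r > τ` on the signed correlation (ties at τ
dropped, negative correlations never kept; an `|r| > τ` policy is available
since the treatment of anticorrelations is a genuinely open choice in the
field).  Weighted matrices keep `r` as the edge weight, binary matrices write
1; diagonals are zero.  No Fisher transform, global-signal regression or
band-pass filtering is applied, and inputs are assumed otherwise
preprocessed.

## Graph measures

The registry holds exactly 27 measures.  Eight are global (assortativity,
characteristic path length, community Louvain, density, global efficiency,
modularity Louvain, modularity finetune, transitivity); the rest return one
value per node.  Three centralities with no weighted counterpart (subgraph
centrality, flow coefficient, k-coreness) are computed on the binary matrix
at the same threshold; all others use the weighted matrix (on a binary
matrix the weighted definitions reduce to the binary ones).

Conventions that matter for VF values:

* **Distances.**  Weighted edge length is `1/weight`; characteristic path
  length and closeness average over reachable pairs only; global efficiency
  treats unreachable pairs as zero efficiency.
* **Attenuations.**  Katz centrality uses `α = 0.9/λ_max`, `β = 1`;
  Bonacich power centrality uses exponent `β = 0.5/λ_max` with the
  `‖c‖² = n` normalisation.  Both α/β are recorded in the result, since VF
  compares values across SP/MP graphs with different spectra.
* **Named-but-undefined measures.**  "Shortcuts centrality" is the fraction
  of a node's edges with edge range > 2 (no alternative path through a
  common neighbour) — an edge-range statistic aggregated per node, flagged
  experimental.  "Get components" reports the size of the node's connected
  component.  "Flow coefficient" is the fraction of a node's neighbour pairs
  not directly connected (paths of length two actually mediated by the
  node), the complement of local clustering.
* **Core–periphery** is a discrete core assignment maximising the
  correlation between the adjacency and the ideal core–periphery pattern by
  seeded greedy single-node flips; the local value is the 0/1 core
  indicator.
* **Modularity family.**  Three seeded Louvain-type routes over the same
  quality Q: single-level Louvain, full multilevel Louvain, and Louvain
  followed by greedy single-node finetuning.  VF consumes the scalar Q;
  community labels are not VF-compatible.
* **Degenerate inputs** raise an explicit undefined-measure error (edgeless
  graphs for path-based measures, regular graphs for assortativity) rather
  than returning silent zeros; batch computation collects per-measure errors.

## Variation factor

Implemented exactly as printed above — mean squared relative difference
× 100, **without** a square root, so VF is not an RMS and grows quadratically
with the relative change.  A subject/parcel pair whose denominator
`(x^MP + x^SP)/2` is exactly zero is undefined under the formula; if the two
values are identical the pair contributes zero (preserving `VF(x, x) = 0`
for any x, including measures that vanish identically on a graph), otherwise
it is excluded from the average and counted.  VF is symmetric in SP/MP and
invariant to joint positive rescaling of both inputs.

## Statistical analysis

One VF per (measure, instance, atlas, dataset, threshold) forms the
long-format stability table.  The MANOVA pivots it wide — observations are
instance × design-cell rows, responses the per-measure VFs — and fits main
effects of the design factors (interactions behind a flag), reporting
Pillai's trace `V = tr[H(H+E)⁻¹]` with its standard F approximation per
factor.  With a single response the trace test degenerates to the classical
univariate F test, which is computed directly in that case.  Post hocs are
unpaired two-sample t tests between factor levels with Bonferroni adjustment
`min(1, p · #pairs)`.

## Synthetic data

Fixtures emulate the real inputs at the topology level: icospheres
(closed, 10·4^k + 2 vertices) stand in for inflated hemispheres;
graph-Voronoi parcellations (multi-source BFS from random seeds, redrawn if
any parcel is smaller than a quarter of the mean — atlases contain no
near-singleton regions) stand in for 64- or 150-region atlases; per-parcel
latent Gaussian signals with block covariance (within-block correlation 0.6,
between-block 0.1, four blocks) plus i.i.d. vertex noise (σ = 1) stand in
for BOLD.  The exact latent covariance is returned for recovery tests: with
σ = 0 and long series the pipeline recovers it to sampling error, and
increasing σ attenuates parcel correlations as `1/(1+σ²/v)`.

Not emulated: hemodynamics, spatially autocorrelated noise, motion,
registration error.  Passing tests therefore demonstrate correctness of the
algorithmic chain and the qualitative stability ordering of measures, not
the numerical VF levels of any real dataset.

## Problem sizes

Default test fixtures use subdivision-3/4 icospheres (642–2,562 vertices),
16–64 parcels, 1–2 subjects, 120–200 time points, and 3–100 instances per
ensemble; the calibration check runs 100-instance ensembles on a
subdivision-5 icosphere.  These sizes keep the full suite and the
reproduction script in the minutes range on a single CPU while exercising
every stage at realistic parcel granularity.
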