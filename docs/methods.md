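# Methods

This note records the statistical procedures implemented in `connstats`,
the conventions chosen where the field admits several, and what the
synthetic-data checks do and do not establish.

## Data model

A subject's connectome is a symmetric nonnegative weighted adjacency matrix
over a fixed parcellation; weights are on a streamline-count scale
(SIFT2-style density weighting makes them non-integer, so weights are
reals).  A pair of parcels is an edge only if at least one streamline
connects them — zero-weight pairs are non-edges throughout.  A cohort adds
group labels (exactly two), behavioral scores (missing values allowed) and
a shared boolean edge mask.

**Group thresholding.**  The mask keeps an edge when its mean weight across
*all* subjects is at least `min_mean_weight` (default 10; the mean exactly
at threshold is kept, matching a strict "fewer than 10 removes" rule) and
at least one subject has nonzero weight.  This suppresses spurious
tractography connections; it is deliberately group-level so that all
subjects share one edge set.

**Outlier screening.**  For sensitivity re-analysis, subjects of a named
group are flagged when their weight deviates from the group mean by more
than 2 sample SDs (ddof = 1, candidate included) on at least 2 edges of a
given edge set.  Degenerate zero-SD edges can never be exceeded.  Note an
arithmetic consequence tested explicitly: in a group of *n*, a lone
outlier's z-score is bounded by (n−1)/√n, so tiny groups cannot produce
2-SD flags at all, and an extreme inflation raises the group SD enough to
push the edge *below* the NBS threshold before screening sees it.
Total-streamline screening is a report (per-subject totals with cohort
z-scores), not an automatic exclusion, since no principled numeric cutoff
exists.

## Network-based statistic

Edge statistics: group design uses the pooled two-sample *t* with the
group2-minus-group1 sign convention, run separately per direction with the
sign arranged so the tested direction gives positive statistics.
Correlation design uses Pearson's *r* against a behavioral variable mapped
to the *t* scale (df = n − 2) so that thresholds are comparable across
designs; |r| → 1 edges are clipped to a maximal finite statistic and
flagged; zero-variance edges get statistic 0 and a flag.

Components are connected components of the suprathreshold graph
(statistic strictly above threshold), sized by extent (edge count) and
intensity (sum of edge statistics).  Both are always computed; one is the
designated primary.  **Intensity is the default primary** because its
permutation distribution is continuous, making the max-statistic p value
essentially exact, whereas extent is integer-valued and its null
distribution is lumpy whenever few edges cross the threshold — at sparse
suprathreshold densities an extent-based test can only be conservative.
An `intensity_excess` flag switches to the sum of threshold exceedances
(statistic − threshold), a convention some toolboxes use; it is off by
default because the plain sum is the stated definition of intensity here.

Permutations shuffle group labels (or the behavioral vector across all
subjects pooled; no covariates, no exchangeability blocks).  Permutation
*i* derives its generator from `(seed, i)`, so runs are reproducible and
chunkable.  The FWE p value of a component is the proportion of
permutations whose maximum component size (same measure) is at least the
observed size; the observed labelling is **not** counted among the
permutations, so p = 0 is possible and is rendered `< 1/n_permutations`.
Intensity comparisons carry a 1e−9 relative tolerance: the observed
component's sum and the permutation accumulator add the same floats in
different orders.

`exhaustive_nbs_test` enumerates every group-label assignment exactly once
(observed included) and is the oracle for the Monte-Carlo test on small
cohorts.

## Graph metrics

Conventions, stated because the literature under-specifies them:

* Weight→length mapping for all shortest-path metrics is the reciprocal,
  `length = 1/weight` (field default for streamline counts); it is isolated
  in one function and swappable.
* Characteristic path length averages finite off-diagonal distances and
  reports the disconnected-pair count; global efficiency averages inverse
  distances with 1/∞ = 0 and is the measure intended to tolerate
  disconnection.
* Weighted clustering is the Onnela geometric-mean-of-triangle-weights
  form with weights normalized by the global maximum; it reduces exactly to
  the binary triangle fraction on 0/1 graphs.
* Betweenness is Brandes on the length graph, normalized by (n−1)(n−2)/2.
* Modularity is maximized by multi-level (Louvain) moves with seeded
  restarts (default 100), keeping the best weighted Q; on 8-node graphs the
  restarts reach the exhaustive-search optimum in ≥ 95% of random
  instances (tested).
* The rich-club coefficient is the weighted variant evaluated at
  binary-degree thresholds k: total weight among nodes of degree > k over
  the sum of the equally many globally strongest weights; NaN when fewer
  than two nodes survive, 0 when they survive without edges.  Note the
  weighted φ of a uniform-weight graph is identically 1, so only weight
  heterogeneity is informative.  A binary variant is intentionally not
  provided as a separate code path; binary graphs fall out of the weighted
  formula.
* Small-worldness is normalized clustering over normalized path length.

## Null models and normalization

Null networks preserve the degree sequence exactly (double-edge swaps, 10
per edge, verified to decorrelate adjacency overlap) and the weight
multiset exactly; node strengths are preserved approximately by placing the
sorted weights greedily: the largest unplaced weight goes to the free edge
with the largest product of residual target strengths, and residuals are
decremented as weights are placed.  The mean relative strength error is
reported per ensemble (< 10% on the fixtures tested; strength correlations
≈ 0.99 on 50-node log-normal graphs).  Graphs with no legal swap (complete
graphs) come back unchanged with a warning.

Normalization divides the observed global metric by the ensemble **mean**
(100 networks by default).  Local metrics are reported raw — normalizing
per-node metrics against rewired nulls is not well defined since node
identity is what rewiring destroys.  The per-k normalized rich-club curve
divides by the ensemble mean of φ(k); the "average rich-club coefficient"
compared between groups is the unweighted mean of φ_norm over the k values
defined in every subject.

## Synthetic cohorts

The generator emulates a two-group structural connectome study:

* **Template**: each pair is connected with probability
  `connection_density` (default 0.35); connected pairs draw log-normal
  weights (log-mean 4.5, log-sd 1.0), putting masked-edge means on the
  ~10–5,000 streamline scale so the default group threshold is exercised.
  These defaults are pragmatic, not fitted — the emulated study does not
  report edge-weight distributions.
* **Subjects**: template × element-wise log-normal noise (log-sd 0.2).
* **Planted effect**: a connected subnetwork (random spanning tree plus
  extra edges; defaults 15 nodes / 30 edges) whose weights are multiplied
  by (1 − `effect_delta`) in the first (patient) group.
* **Behavior**: group-wise normal draws using the published cohort's
  means/SDs (ASRS inattention 23.36/5.08 vs 12.78/5.54, hyperactivity-
  impulsivity 19.58/7.27 vs 10.19/4.96, commission errors 17.77/7.01 vs
  10.22/5.48, patients n = 40 vs controls n = 36); omission errors from a
  negative binomial calibrated to median 1, IQR 0–3 vs 0–1, to exercise the
  nonparametric branch.  Error counts are rounded and floored at 0.
  Commission errors can additionally be shifted by
  `behavior_edge_coupling` × the cohort-standardized mean weight of the
  planted edges (default coupling 0 keeps the published calibration exact;
  a negative coupling produces the hypoconnectivity-more-errors pattern).
* **Seeding**: one seed per cohort; plant/template/subject/behavior streams
  are independent children of it, so cohorts are bit-reproducible.

What the generator does **not** emulate: spatial embedding of parcels,
distance-dependent connection probability, correlated edge noise within
subjects (edges are conditionally independent given the template), or
hemispheric structure.  Consequently, passing recovery and calibration
checks demonstrates the statistical machinery is correct and calibrated
under exchangeability and log-normal noise — not that real acquisition
artifacts (motion, seeding bias) are handled; those belong upstream.
Because per-edge noise is independent, edge-level correlations with a
behavioral variable coupled to a k-edge network mean are diluted by 1/√k —
behavioral-design demonstrations therefore couple few edges.

## Problem sizes in the reference computations

The acceptance computations use: FWE calibration on 200 null cohorts of 60
nodes, 20 + 20 subjects, 500 permutations, threshold 3.0 (the calibration
property is size-free once the primary measure is continuous, so a compact
network size is used); planted recovery on 20 cohorts at the full preset —
164 nodes, 30-edge planted subnetwork, `effect_delta` 0.5, 20 + 20
subjects, 1,000 permutations.  The pipeline's own defaults remain the
study-scale values (10,000 permutations, 100 null networks, thresholds
3.0/3.5/4.0, α = 0.05).

## Known limitations

* The greedy strength-preserving weight placement is O(m²) per null
  network; full-size (164-node, ~4,700-edge) ensembles of 100 networks per
  subject are minutes of work, so exploratory runs should lower `n_null`.
* Extent-based FWE p values are conservative when suprathreshold edges are
  rare (see above); this is a property of the statistic, not the
  implementation.
* The correlation-design effect size reported for a significant network
  (Cohen's d on group-split network mean connectivity) is a descriptive
  companion, not part of the permutation inference, and is labelled as
  such in reports.
* One-tailed designs are run as separate analyses per direction; the
  reported p values are not corrected across the two directions or across
  thresholds, matching common NBS practice.
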