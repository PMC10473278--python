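# Methods

This document records the statistical models, parameter defaults, and
numerical conventions used throughout `netrel`. Everything stated here is
implemented and exercised by the test suite; no empirical claim is made that
the package does not itself compute.

## 1. Frequency bands

The slow bands are log-linear in natural frequency: slow-k spans
`(e^(-k+0.5), e^(-k+1.5)]` Hz for k = 1…6, so adjacent bands share edges and
each is `e` times wider than the next-slower one. The slow-6 lower edge is
floored at `e^-5 ≈ 0.0067` Hz (configurable) rather than `e^-5.5`, keeping at
least one full cycle in scans of a few hundred seconds.

**Grid snapping.** A scan of `T` volumes at repetition time `tr` has DFT
frequency resolution `1/(T·tr)` Hz. Each theoretical edge `f` is snapped to
the nearest bin index `i = floor(f·T·tr + 0.5)` (half-up on exact ties).
Bands are half-open in bin index — bin `i` belongs to slow-k iff
`low_bin < i ≤ high_bin` — so the snapped bands exactly partition the
strictly-positive-frequency grid up to Nyquist. For `T = 1200`, `tr = 0.72 s`
this yields lower edges 0.0069, 0.0116, 0.0301, 0.0822, 0.2234, 0.6065 Hz
for slow-6 … slow-1. A band containing the Nyquist bin is truncated there
and suffixed `-` (slow-1- has upper edge 0.6944 Hz at this geometry); bands
entirely above Nyquist are omitted with a warning, as are bands narrower
than one bin (possible at short T). The fixed empirical band
`slow-emp = (0.01, 0.08)` Hz is available alongside the partition.

**Filtering.** Band-pass filtering multiplies the real FFT by the 0/1 bin
mask and inverts — a brick-wall filter. Consequences: components of distinct
bands are exactly orthogonal, and components + residual + DC reconstruct the
input to floating-point accuracy (tested at 1e-10 relative). Brick-wall
masking has ringing in the time domain; it is used deliberately because the
pipeline consumes full-scan correlations, not time-resolved signals.

## 2. Connectivity

Edges are Pearson correlations `r_ij` between nodal time series. Zero-
variance nodes produce correlation 0 with a warning. Correlations are mapped
to non-negative weights via Fisher z (`z = atanh(r)`, with `|r|` clipped at
`1 − 1e-7`):

- `pos`: `max(z, 0)` — negative edges discarded;
- `abs`: `|z|` — magnitude only;
- `exp`: `e^z` — order-preserving, strictly positive;
- `div`: `c / sqrt(2(1 − r))` on the raw correlation — inverse of the
  correlation distance `sqrt(2(1−r))`; the constant `c` defaults to 2 and is
  configurable (`div_constant=1` gives the plain reciprocal distance).

After edge filtering, the surviving edges can be kept `weighted`, rescaled
to `normalized` (divide by the maximum surviving weight), or `binary`.

## 3. Edge filtering

All schemes order candidate edges by weight descending, ties broken by
lexicographic node pair `(i, j)` — every filter is deterministic.

- `ABS_05` keeps edges whose **source correlation** exceeds 0.5 (the
  threshold is defined on `r`, before the non-negativity transform).
- `PROP_p` keeps the `round(p · N(N−1)/2)` strongest edges; `DEG_K` keeps
  `round(K · N/2)` (mean degree K). Rounding is half-up.
- `GCE` sweeps edge-count prefixes of the ordering and keeps the prefix
  maximizing `J = Eg − ρ` (binary global efficiency minus edge density).
- `ECO` maximizes `(Eg + Eloc)/ρ` over the same prefixes. Both sweeps use
  exact early stopping: since `Eg, Eloc ≤ 1`, `J ≤ 1 − ρ` and
  `(Eg+Eloc)/ρ ≤ 2/ρ`, so the sweep stops once the bound for all remaining
  prefixes falls below the best value seen — the argmax is unchanged. ECO
  re-computes local efficiency only for nodes whose neighborhood the new
  edge touched. Near-equal objective values can make the argmax sensitive to
  floating-point rounding among exactly tied prefixes; tests compare by
  objective value.
- `MST` is the maximum-weight spanning tree (Kruskal with union–find),
  equivalent to the minimum spanning tree of distances `1/w`.
- `OMST` extracts successive edge-disjoint MSTs; after each round the
  aggregate is scored by `J = Eg − ρ` with `ρ` the **retained-weight
  fraction** (not density), and the aggregation with maximal J is returned.
- `PMFG` inserts edges strongest-first, keeping each iff the graph remains
  planar (networkx incremental planarity check), until `3(N−2)` edges.
- `TMFG` seeds a maximum-total-weight 4-clique and repeatedly inserts the
  vertex–face pair with maximal weight gain, splitting the face; it yields a
  planar chordal graph with exactly `3(N−2)` edges. The seed clique search
  is exhaustive (vectorized) for `N ≤ 120` and greedy above; face tie-breaks
  are by gain, then lowest vertex, then earliest face.
- `OTMFG` runs edge-disjoint TMFG rounds with previously selected edges
  barred, aggregated with the same weight-fraction J-argmax rule as OMST.

## 4. Graph metrics

Shortest-path metrics use Dijkstra on edge lengths `1/w` (the `reciprocal`
convention, default) or hop counts (`unit`); binary graphs always use hop
counts. Disconnected pairs contribute 0 to efficiencies and are excluded
from path-length and diameter averages (graphs are flagged `disconnected`).
Empty graphs return all-zero metrics flagged `degenerate_empty`.

- Global efficiency `Eg`: mean of `1/d` over distinct pairs.
- Characteristic path length `Lp`: mean distance over reachable pairs.
- Diameter `D`: exact maximum distance up to 200 nodes; a double-sweep
  lower bound above that (documented trade-off; all in-repo uses are exact).
- Clustering `Cp`: mean nodal clustering; weighted graphs use the Onnela
  geometric-mean form (via networkx) on weights normalized by the maximum.
- Local efficiency `Eloc`: mean over nodes of the global efficiency of the
  neighborhood subgraph.
- Transitivity `Tr`: binary triangle ratio `3·triangles/triads`.
- Modularity `Q`: best of 10 seeded Louvain runs (seeds `seed…seed+9`),
  deterministic given the seed. Louvain is a heuristic for an NP-hard
  optimum; tests verify the returned Q is the true modularity of the
  returned partition and does not exceed the exhaustive maximum on small
  graphs, not that the optimum is always attained.

Nodal metrics: nodal path length and efficiency, local efficiency,
clustering, PageRank (damping 0.85, sums to 1), degree/strength, eigenvector
centrality (principal eigenvector of the adjacency, unit norm), resolvent/
Katz centrality (`(I − αA)x = 1` with `α = 0.9/λ_max`), subgraph centrality
(`diag(e^A)`), and unnormalized shortest-path betweenness.

## 5. Reliability model

For metric value `φ_ijk` (measurement i, visit j, subject k):

```
φ_ijk = γ000 + p0_k + v0_jk + e_ijk
p0 ~ N(0, σ²_subject), v0 ~ N(0, σ²_visit), e ~ N(0, σ²_residual)
```

The **dependability ICC** is `σ²_subject / (σ²_subject + σ²_residual)`:
visit-level variance is treated as a systematic session effect and excluded
from the denominator (an inclusive variant is available via
`include_visit_variance=True`). The variability anatomy normalizes by the
full total: `Vb = σ²_subject/σ²_total`, `Vw = σ²_residual/σ²_total`.

**Estimation.** For balanced designs without covariates the components come
from the closed-form nested-ANOVA method of moments

```
σ̂²_e = MSE,  σ̂²_v = max((MSV − MSE)/n, 0),  σ̂²_p = max((MSP − MSV)/(nM), 0)
```

which coincides with REML in the interior of the parameter space for
balanced nested designs (verified against statsmodels in the tests at
~1e-3 relative). Unbalanced tables or covariate adjustment use statsmodels
`MixedLM` (REML, random intercept per subject, visit as a variance
component). Covariates (age, sex, inter-visit interval) are standardized
for fitting and slopes reported on the original scale. Degenerate designs
(one measurement per visit, or one visit) fall back to the identifiable
two-level decomposition with the confounded component set to zero.

**Uncertainty.** The CI is a subject-level (cluster) percentile bootstrap:
resample subjects with replacement, refit, take the 2.5/97.5 percentiles of
the ICC. The balanced path is fully vectorized across replicates. Measured
coverage of the nominal 95% interval is ≈ 92% at the default design scale
(41 subjects) — percentile bootstraps of variance ratios are mildly
anti-conservative at this sample size; this is a property of the method,
not a bug, and is reflected in the acceptance threshold (≥ 90%).

**Qualitative levels.** slight (0, .2], fair (.2, .4], moderate (.4, .6],
substantial (.6, .8], almost perfect (.8, 1].

**Reliability gradient.** For two pipeline results, the vector
`(ΔVw, ΔVb)` is classified by quadrant: II (`ΔVb > 0, ΔVw < 0`) optimal,
I and III suboptimal, IV adverse; angle `θ = atan2(ΔVb, ΔVw)`, magnitude
`|ΔICC|`. Axis-aligned changes have no quadrant.

## 6. Synthetic cohort generator

Metric-level tables draw directly from the three-level model with chosen
variances, optional fixed covariate effects, and covariates
`age ~ U(22, 35)`, `sex ~ Bernoulli(0.5)`, `interval ~ U(18, 328)` days.

Time-series cohorts start from a block-modular group correlation matrix
(4 modules, within-module r = 0.5, between-module r = 0.1 by default).
Subject matrices add a symmetric Gaussian perturbation of scale `η_b`
(`subject_dev_scale`, default 0.2); each scan adds a further perturbation of
scale `η_w` (`scan_dev_scale`, default 0.1); both are followed by PSD repair
(eigenvalue clipping plus re-normalization to unit diagonal). Scans are
stationary Gaussian series with the scan covariance, spectrally masked to
the requested bands (default equal power in slow-5 and slow-4) and
normalized to unit variance. Default design: 41 subjects × 2 visits × 2
measurements, 60 nodes, 1,200 volumes, TR = 0.72 s.

**Realism and limits.** The generator reproduces the features the pipeline
is sensitive to — modular correlation structure, a controllable between/
within-subject variance hierarchy, band-limited spectra — and is verified
to put > 90% of spectral power in the configured band and to yield more
reliable edge patterns as `η_b/η_w` grows. It does **not** model
hemodynamic autocorrelation, motion or physiological artifacts, scanner
drift, non-Gaussian amplitudes, or realistic inter-regional distance
effects; absolute ICC magnitudes from synthetic cohorts are not predictions
for real fMRI.

## 7. Grid evaluation and statistics

`run_grid` crosses bands × transforms × filters × weight schemes × metrics
(row count equals the product), computing each scan's metric vector once
per cell and estimating the ICC per metric. Failures are isolated per cell
with a warning. Cells are cached by a content hash of the cohort and the
cell descriptor, so reruns and resumption are cheap; per-cell bootstrap
seeds derive from a master seed through `SeedSequence` (all seeds < 2³¹).

Choice comparison treats every full crossing of the non-tested factors
(plus metric) as a block. The Friedman statistic uses the mid-rank formula
`χ² = 12/(nk(k+1)) Σ R_j² − 3n(k+1)` with `df = k−1` and Kendall's
`W = χ²/(n(k−1))`; it is computed in-package because scipy's tie correction
differs from this form (they coincide on tie-free data, which the tests
check). The p-value uses the χ² approximation. Pairwise Wilcoxon
signed-rank tests report the positive-rank sum V, effect size
`r = |z|/√n` from the tie-corrected normal approximation, and two-sided
p-values (exact for < 10 non-zero pairs, matching full sign enumeration in
the tests), Bonferroni-multiplied by the number of level pairs.

`power_min_n` implements the Walter–Eliasziw–Donner approximation for a
one-sided test of `ICC > ρ0` with k repeats:

```
n = 1 + 2k (z_{1−α} + z_{1−β})² / ((k−1) (ln C0)²),
C0 = (1 + k·ρ0/(1−ρ0)) / (1 + k·ρ1/(1−ρ1))
```

rounded half-up to an integer; (ρ0=0, ρ1=0.2, k=4, α=0.05, power=0.8)
gives n = 35.

## 8. Numerical conventions and problem sizes

- All randomness flows through `numpy.random.default_rng` / `SeedSequence`;
  every public stochastic function takes a seed and is reproducible.
- Edge ordering ties: weight descending, then `(i, j)`; prefix-sweep
  argmax ties: earliest prefix.
- Exact diameter to 200 nodes; exhaustive TMFG seed clique to 120 nodes;
  these bounds exceed every design used in-repo (≤ 60 nodes).
- ICC estimates are clamped to `[0, 1)`; negative method-of-moments
  components are truncated at zero.
- Parameter-recovery accuracy at the default scale (41 subjects): estimator
  bias ≤ 0.023 absolute across true ICC 0.1–0.9 (50 cohorts per point);
  per-cohort absolute error is dominated by sampling variance
  (`SD(σ̂²_p) ≈ σ²_p · sqrt(2/(P−1))`), which no estimator can remove.
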