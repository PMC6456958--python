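# Methods

`phyllonet` re-implements, as a tested library, the statistical core of a
two-compartment leaf-mycobiome analysis: host/fungus preference statistics
and bipartite network architecture indices, both judged against a
label-shuffling permutation null, plus indicator species analysis and a
synthetic community generator that makes every stage testable without
sequencing data.

## Data model and preprocessing

The pipeline starts from a sample x OTU integer read-count table with
per-sample metadata (host plant species, compartment: epiphyte/endophyte).
Preprocessing is deterministic given a seed and runs in a fixed order:

1. **Low-count OTU filter** — OTUs with a pooled read total below 10 are
   removed (PCR/sequencing-noise guard). The pooling scope is configurable
   (`pooled` across all samples, or `per_compartment`).
2. **Rarefaction** — every sample is subsampled *without replacement* to a
   common depth (default: the smallest sample total), one multivariate
   hypergeometric draw per sample. Depth is conserved exactly and presences
   can only be lost, never created.
3. **Binarization and species-level collapse** — presence/absence per
   sample, then the plant-species x OTU *species-level matrix* whose cell
   (s, o) counts the samples of species s containing OTU o. Cells are
   bounded by the per-species sample count (`row_capacity`).

The preference and network analyses run on the rarefied, filtered table by
default, matching the preprocessing order above; callers who want the
pre-rarefaction presences can pass those matrices explicitly — every
analysis function takes the matrix it consumes as an argument.

Community summaries (per-sample richness, Hellinger transform, Bray-Curtis
dissimilarities, sample-based rarefaction curves, compartment
specific/shared OTU partition) use the standard definitions; Bray-Curtis is
delegated to `scipy.spatial.distance` with the all-zero-pair distance
defined as 0.

## The permutation null

One randomization scheme feeds every downstream test: plant-species labels
are permuted uniformly at random across samples (sample rows untouched) and
the species-level matrix is rebuilt. This conserves each species' sample
count and each OTU's total occurrence, so any structure tied to *which*
host a sample came from is destroyed while everything else is kept. The
same engine serves the preference statistics and the network randomization
tests; the scheme field is the hook for alternative nulls, which are out of
scope. Replicates are independent draws (not guaranteed distinct — with 48
samples, collisions are negligible). Ensemble SDs use the sample (n-1)
denominator throughout.

## Host/fungus preference

**d′** is the Kullback–Leibler specialization of a focal species'
interaction frequencies against partner availability, rescaled between the
minimum and maximum achievable given the marginals:
d_i = Σ_j p′_ij ln(p′_ij/q_j) with p′_ij = a_ij/A_i, q_j = A_j/A_tot;
d′ = (d_i − d_min)/(d_max − d_min), d_max = ln(A_tot/A_i) (analytic bound),
d_min from a greedy integer allocation of A_i proportional to availability
(floor of A_i·q, then one unit at a time on the cell minimizing the
divergence, lowest index on ties). d′ of a zero-total focal species is
undefined (NaN). Note a structural property of this normalization: when one
axis pools many partners (a host row aggregating hundreds of OTUs), a
perfect single-host specialist attains d = ln(A_tot/A_hostrow) < d_max, so
its d′ plateaus near 0.5 rather than 1; d′ = 1 requires the focal total to
match its partner's total. The standardized d′,
(d′_obs − mean d′_null)/sd d′_null, is what the analyses report, which makes
the plateau irrelevant for inference.

**2DP** (two-dimensional preference) standardizes each plant x OTU cell of
the species-level matrix the same way: (N_obs − mean N_null)/sd N_null. A
cell whose null SD is zero (e.g. an OTU present in every sample, so every
permutation yields the same cell value) is *undefined* and reported as
missing, never as a number. Permutation P values use the add-one convention
(observed counted among the replicates, so P ≥ 1/(n_perm+1)); two-tailed by
default (`tails` exposes one-tailed variants) because both preference and
avoidance are of interest. P values are Benjamini–Hochberg FDR-adjusted
across cells, and the dataset-derived "strong preference" boundary is the
smallest |2DP| among FDR-significant cells — it is computed from the data,
never hard-coded.

## Network architecture indices

Five indices are computed on the species-level matrix (rows = plants,
columns = OTUs). Following the toolchain conventions this package mirrors,
modularity and the checkerboard score run on the binarized matrix and the
other three on the quantitative one; both choices are arguments.

* **Weighted connectance** — Bersier-style quantitative linkage density
  LD = ½[Σ_j (b_·j/b_··)·2^{H_j} + Σ_i (b_i·/b_··)·2^{H_i}] (H = Shannon
  entropy, base 2, of the focal line's weight distribution) divided by
  (rows + columns).
* **H2′** — network-level specialization: (H2_max − H2)/(H2_max − H2_min)
  with H2 the Shannon entropy of the interaction distribution.  H2_min
  comes from a greedy concentration fill (repeatedly place
  min(max row remainder, max column remainder); each step exhausts a line).
  H2_max comes from the floor of the independence fill r_i·c_j/total with
  marginal deficits repaired one unit at a time on the largest fractional
  remainder among deficit rows/columns.  On small matrices (≤ 64 cells),
  where integer granularity makes the constructive fills noticeably
  suboptimal, both fills are refined by steepest-ascent 2×2 swap moves
  (marginal-preserving unit exchanges) until no move improves the entropy;
  and since the observed matrix is itself a feasible fill, the bounds are
  additionally clamped so that H2_min ≤ H2 ≤ H2_max always holds.  All
  fills are deterministic (lowest index on exact ties).  Because the
  integer rounding depends weakly on the grand total, H2′ is scale- and
  permutation-invariant only to ~0.02 (the other four indices are exactly
  invariant); the fills sit within 0.02 of exhaustive-search bounds on
  small instances.  A single-cell network has H2_max = H2_min and is
  reported as 0, flagged degenerate.
* **WNODF** — rows and columns ranked by decreasing totals; an ordered pair
  (upper u, lower l) with strictly larger upper total contributes
  100 · #{k: 0 < w_lk < w_uk}/#{k: w_lk > 0}, ties in totals contribute 0,
  empty lower lines contribute 0; the mean over all row and column pairs.
* **Barber modularity Q_B** — (1/F) Σ_ij (A_ij − k_i d_j/F) δ(g_i, g_j) on
  the binary matrix, maximized over joint row/column partitions.  Three
  optimizers share the objective: (1) seeded simulated annealing
  (`barber_modularity`, the default entry point): geometric cooling T0 = 1,
  factor 0.9, 25 proposals per node per temperature, floor 1e-3, early stop
  after 10 temperatures without an accepted move, 8 restarts; moves are
  single-node reassignments plus whole-module merges (splits are reachable
  through single-node moves), and each restart ends with a deterministic
  coordinate-ascent polish.  (2) restarted BRIM coordinate ascent
  (`brim_modularity`): alternately reassign all columns given rows and vice
  versa to the best-gain module, parking nodes with negative best gain in
  singletons; fast enough to run on every permutation replicate.
  (3) exhaustive enumeration of all set partitions (`exhaustive_modularity`,
  ≤ 10 nodes), the oracle the other two are tested against.
* **C-score** — Stone–Roberts checkerboardedness: the mean over species
  pairs of (R_i − S_ij)(R_j − S_ij) on the binary matrix, along either axis.
  The standalone `cscore` operation reports raw checkerboard units by
  default; the network-level randomization pipeline defaults to the
  *normalized* variant (each pair's units divided by R_i·R_j), matching the
  default of the reference R toolchain and taming the raw statistic's heavy
  tail — both layers expose the flag.  In raw units the total checkerboard
  count is the same whether accumulated over row pairs or column pairs, so
  the two axes give identical Z-scores; the per-pair normalization breaks
  that identity, and the normalized axes are reported separately.

## Randomization tests and cross-network comparison

Each index is evaluated on the observed matrix and on every null replicate
with identical settings — in particular the same modularity optimizer with
the same restart budget on both sides, so optimization quality cancels.
The report carries, per index: the observed value, null mean/SD/SE, the
one-sample t statistic of the replicate values against the observed value
with its two-tailed P (the only t-test reading consistent with one observed
network per compartment; Welch is not applicable), an add-one two-tailed
*empirical* permutation P, and the Z-score (observed − null mean)/null SD.
The t statistic gains ensemble-size precision (its SE shrinks as
1/sqrt(n_perm)), so it flags even tiny departures; the empirical
permutation P is the statistic that is calibrated at its nominal level
under the null, and it is what the calibration tests check. Cross-network
comparison is by Z-score sign and magnitude per index, with a plain-verdict
column (higher H2′ Z → more specialized, lower WNODF Z → more strongly
anti-nested, and so on).

## Indicator species analysis

Dufrêne–Legendre IndVal on relative abundances: specificity (group mean
relative abundance over the sum of group means — group-equalized, so
unequal group sizes do not bias it) times fidelity (fraction of the group's
samples containing the OTU). Each OTU reports its best group; significance
is an add-one permutation P of the per-OTU maximum under group-label
shuffling (default 1000 permutations, matching the rest of the pipeline);
strong indicators have IndVal > 0.6 and P < 0.05.

## Synthetic communities

The generator emulates the processed design of the emulated study: 6 plant
species x 8 replicate samples per compartment, a few hundred OTUs, all
samples at one read depth. Per OTU: a lognormal base abundance
(σ = 2.5 — chosen so the ~40 most abundant OTUs carry ≈ 88% of reads, the
dominance structure such surveys show; σ = 1.2 would make the community far
too even and saturate every presence), a specialist flag (fraction
`fraction_specialists`, default 0.8 — in the emulated system the large
majority of abundant interior-leaf OTUs show significant host preference,
so a mostly host-responsive pool is the realistic default; θ then sets how
strong that response is per compartment), and for specialists a uniformly
drawn focal host. The host weight profile is
w(h) = (1−θ)/n_hosts + θ·δ(h = focal): exactly uniform at θ = 0 (labels
exchangeable — the null-calibration regime) and single-host at θ = 1. Per
sample, each OTU independently survives a dropout draw (occupancy noise,
default 0.2), and the read vector is one multinomial draw of the configured
depth over the surviving expected mixture — depth is conserved exactly.

`generate_compartment_pair` builds an epiphyte-like (θ = 0.3) and an
endophyte-like (θ = 0.8) table over a partially shared OTU pool (default
shared fraction 0.4), the configuration under which the downstream
comparison is expected to show the interior network more specialized and
modular, less connected, more anti-nested, and more checkerboarded.

What the generator does *not* emulate: phylogenetic signal in host
affinity, spatial/environmental covariance between samples, compositional
correlations beyond the multinomial, or sequence-level artifacts. Passing
tests therefore demonstrate correctness and calibration of the statistics
under a clean host-filtering model, not robustness to those real-data
features.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng`; the CLI fans a
  single run seed out to fixed per-stage child seeds via `SeedSequence`
  (documented stage codes), so each stage is independently reproducible and
  rerunning a stage with the same seed and config is byte-identical
  (outputs contain no timestamps).
* Permutation P values never reach 0 (add-one convention); FDR adjustment
  is the Benjamini–Hochberg step-up via statsmodels.
* Undefined quantities (zero null SD, zero-total focal species) are NaN
  plus an explicit flag, never a substituted number.
* Degenerate inputs: zero-total rows map to zero under Hellinger; all-zero
  networks are rejected; empty fill lines contribute zero to WNODF; metric
  evaluation inside ensemble sweeps converts per-replicate degeneracies to
  NaN and errors out if more than 1% of replicates are affected.

## Problem sizes used in the shipped checks

The calibration and recovery checks run at a scaled-down version of the
study design chosen to keep the full suite fast on one CPU while leaving
the statistics in the same regime: 6 species x 8 samples per compartment
throughout; ~100 OTUs per compartment at depth ≈ 800–2300 (the study's
reads-per-OTU ratio is ≈ 23:1; these sizes bracket it); 1000 permutations
for preference and compartment-pair recovery, 200 for the rejection-rate
outer loop (which repeats over ~100–200 independent null datasets). The
null-calibration summary pools several independent datasets so the
empirical mean/SD estimates are not dominated by single-dataset sampling
noise (per-OTU standardized scores within one dataset share that dataset's
sampling fluctuations).

## Known limitations

* The H2′ bounds are heuristics (exact only against small-instance
  exhaustive search to 0.02); an LP/flow-based exact integer bound is out
  of scope.
* Annealing and BRIM are local optimizers; equality with the exhaustive
  maximum is verified on ≤10-node graphs, and on larger graphs Q_B is a
  lower bound on the true optimum (identical settings on observed and
  replicates keep comparisons fair).
* The one-sample t against the observed value is reported for completeness
  but is not a calibrated test (see above); use the empirical permutation P
  or the Z-score for inference.
* No degree-preserving quantitative nulls (Patefield-style) — the scheme
  hook exists, but only label shuffling is implemented.
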