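# Methods

This note documents the models, numerical choices and limitations behind
`gfnet`, in the spirit of a statistical software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Connectome construction

**Structural.** Probabilistic tractography estimates the two directions of
every connection independently; we average them and divide by the mean
voxel size of the two parcels, `w(a,b) = mean(counts_ab, counts_ba) /
mean(size_a, size_b)`. The diagonal is stored as zero in both modalities: a
region's connectivity with itself carries no information. Two exact laws
follow and are tested: transposing the count matrix leaves the network
unchanged, and scaling all parcel sizes by `c` scales every weight by
`1/c`.

**Functional.** The band-pass filter is a windowed-sinc (Hamming) FIR of
odd length ≈ 3 cycles of the low band edge, applied centred so it is
exactly zero-phase — envelopes are not time-shifted, which matters because
Pearson correlation at lag zero is the connectivity statistic. The filter
is applied by FFT convolution with reflect padding; the symmetric impulse
response makes a single centred pass equivalent to a forward–backward
pass. The envelope is the magnitude of the analytic (Hilbert) signal.
Half a filter length is discarded at each end before correlation
(configurable), absorbing edge transients. The delta band's 0.1 Hz edge
needs ~4,500 taps at 150 Hz; inputs must be at least three filter lengths
long, which in practice means ≥ 5 min recordings for delta.

The gamma band is nominally 32–75 Hz, but at the 150 Hz effective sampling
rate 75 Hz sits exactly at Nyquist; the upper edge is capped at
`0.95·fs/2` (71.25 Hz) wherever the band is used.

No orthogonalization or source-leakage correction is applied before
envelope correlation; the pipeline reproduces the plain
envelope-correlation definition. Negative envelope correlations are
clipped to zero before modularity, segregation and path metrics (standard
practice for nonnegative-weight graph measures on MEG envelope networks);
the signed matrix is preserved in the functional `WeightedNetwork` itself.

## Graph measures

Modularity follows Newman–Girvan; community detection is Newman's
leading-eigenvector method: recursive bisection along the sign of the
leading eigenvector of the (generalized, for subgraphs) modularity matrix,
with Kernighan–Lin node-move refinement after each split (on by default,
`refine=False` for a strictly spectral solution). Numerical rules: a
leading eigenvalue ≤ 1e−10 rejects the split; eigenvector entries exactly
zero go to the positive side; a split is kept only if it increases Q by
more than 1e−12. The fallback is the single-module partition (Q = 0), so
the returned Q is never negative. The implementation is verified against a
brute-force double sum (to 1e−12), an exhaustive search over all
partitions at n = 8 (gap ≤ 0.02), and igraph's independent
implementation.

Path metrics use edge length `1/w` (the Brain Connectivity Toolbox
convention); characteristic path length averages finite ordered-pair
distances and reports the unreachable-pair count instead of returning
infinity, which keeps pruned or sparse synthetic graphs usable. Global
efficiency defaults to the mean inverse distance over ordered pairs
(`1/∞ = 0`); the literal "inverse of the characteristic path length"
variant is exposed as `method="inverse_cpl"` since the two verbal
definitions circulate interchangeably but coincide only on
distance-transitive graphs. Local efficiency averages, over nodes, the
global efficiency of the subgraph induced on each node's neighbours; nodes
with fewer than two neighbours contribute zero. Density binarizes after
removing the weakest `ceil(0.01·E)` edges — the ceiling guarantees "remove
the weakest 1 %" removes at least one edge whenever edges exist — with
ties broken by node-index order for determinism.

The segregation coefficient of node `a` is its within-module strength over
its total strength, computed against a group-level partition. Isolated
nodes have no defined ratio and are returned as NaN; the permutation test
drops such ROIs listwise and records them.

## Inference

**Group split.** Subjects above the cohort-mean Gf form the high group.
The separation of the resulting group means is reported in units of the
standardized test SD (15); below 1.0 it warns but does not fail, since the
psychometric guideline is advisory. With the generator's default
population parameters (117.72 ± 4.66 vs 102.98 ± 6.09 at n = 38/31) the
labelled separation is ≈ 0.98 SD and the Welch t from the summary
statistics is ≈ 11.08 on ≈ 55 df.

**Node-metric MCS.** The observed statistic is the pair of counts of ROIs
with positive / negative high-minus-average median difference; group
labels are permuted (sizes preserved) and each tail's p-value is the
add-one-smoothed proportion of permutations whose count *strictly exceeds*
the observed one. Exceedance (rather than ≥) is deliberate: the count
statistic is heavily tied — with equal groups, any permutation retaining a
majority of true high-group members reproduces a saturated count exactly —
and under ≥ a maximal observed count could never reach the add-one floor
`1/(n_perm+1)` that an overwhelming effect should attain. An observed
count of zero is never evidence and gets p = 1. Median differences exactly
zero count in neither tail. Swapping the group labels exchanges the
positive and negative tails exactly (same seed), a property the tests
assert. Calibration under the null is verified by simulation (200
replicate no-effect cohorts, two groups of 20, 90 ROIs, 2,000
permutations — scaled from the 10,000 default to fit a desk-scale run):
the empirical positive-tail type-I error at the corrected level 0.025 must
lie within two Monte-Carlo standard errors.

**Modularity null.** The group-mean matrix's upper-triangle weights are
shuffled uniformly (preserving the weight multiset and symmetry), the
leading-eigenvector Q recomputed per permutation, and the observed Q
declared significant only above the 99.9th percentile of the permuted
values. A degree-preserving weight shuffle is available as an alternative
null (`method="degree_rewire"`) but matrix permutation is the default. On
a uniform complete network every permutation equals the original, so the
strict-percentile rule correctly never fires.

**ANCOVA.** `value ~ group + sex + age + education`, type-II sums of
squares, no interactions (none are part of the design), via statsmodels
OLS. Rank-deficient designs fail with the collinear columns named;
zero-residual fits are flagged degenerate rather than returning undefined
F statistics. SC–FC coupling correlates the vectorized upper triangles of
each subject's structural and band-specific functional matrices and feeds
the per-subject r into the same ANCOVA.

## Synthetic cohorts

The generator's defaults are the study conditions: 90 ROIs, groups of
38/31, Gf scores N(117.72, 4.66²) / N(102.98, 6.09²), ages, education
years and sex composition drawn from the corresponding group summaries,
150 Hz sampling, 10 min recordings, five canonical bands. Where the
upstream physiology is not modelled, the generator emulates its *outputs*:

- **Tractography.** A planted module partition (default: five equal
  contiguous blocks) sets intra/inter mean weights (0.5 / 0.1, a
  realistic ~5:1 within:between contrast for size-normalized streamline
  networks); expected counts are the planted weight times the pairwise
  mean parcel size (sizes uniform on [200, 2000] voxels, shared across a
  cohort as atlas parcels are), and each *direction* receives independent
  truncated-normal noise (SD 25 counts), making the raw matrix
  asymmetric exactly as independent per-direction estimation does. With
  zero noise, counts are left unrounded so the normalized network equals
  the planted weights bit-exactly — the identity several tests rely on.
  Group effects: `group_degree_shift` adds to every high-group edge
  weight, `group_inter_shift` only to inter-module edges.
- **Band time series.** Each region is `envelope × carrier`. The envelope
  is an exponentiated low-pass Gaussian process — strictly positive, as an
  amplitude must be, with cutoff `min(0.5 Hz, bandwidth/4)` so modulation
  stays slow relative to the carrier. Latent Gaussian correlations are
  chosen by inverting the lognormal correlation map
  `corr(e_i,e_j) = (exp(σ²ρ)−1)/(exp(σ²)−1)` (σ = 0.5 by default), so the
  population envelope correlation equals the requested target matrix
  (validated symmetric PSD, unit diagonal). The carrier is a
  constant-modulus FM cosine whose instantaneous frequency is low-pass
  noise wandering inside the band (deviation 25 % of the half-width,
  clipped 5 % inside the edges). A constant-modulus carrier is essential:
  band-filtered Gaussian noise carries its own Rayleigh-distributed
  envelope, independent across regions, which multiplies into the
  recovered envelope and shrinks an 0.8 planted correlation to ≈ 0.6;
  extracting only the phase of filtered noise still loses ≈ 0.18 through
  phase slips. With the FM carrier the full analysis path (band-pass →
  Hilbert → Pearson) recovers planted 0.8 blocks to within ±0.01 at 120 s
  (300 s for delta), comfortably inside the ±0.1 contract the acceptance
  checks enforce. Per-band functional group effects are planted as
  additive offsets on the high group's target correlations
  (`band_fc_shift`).

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: source-leakage correlations between
nearby regions, 1/f spectral shape and band co-occupancy (each synthetic
series lives in one band), non-stationary artifacts, heavy-tailed count
noise from crossing fibres, or any dependence of connectivity on Gf beyond
the planted shifts. Results on synthetic cohorts validate the *machinery*
(estimators, tests, calibration), not neuroscientific conclusions.

## Determinism and problem sizes

Every random stage takes an explicit seed; a master seed expands into
per-stage child seeds keyed by stage/subject/band tags, so adding a stage
never perturbs another's stream. Identical config + seed reproduces a
pipeline report bit-for-bit, including across a write-to-disk /
reload-from-files round trip (matrix CSVs round-trip doubles exactly).

Simulation sizes used by the test suite and acceptance script — chosen as
the smallest scales at which the Monte-Carlo bounds above are meaningful:
MCS calibration at 200 replicate cohorts × 2,000 permutations; modularity
null at 20 seeds × 200 permutations (scaled from the 1,000 default);
envelope recovery at 12 regions × 20 seeds per band; exhaustive partition
search at n = 8; brute-force modularity at n = 6 × 100 graphs.

## Known limitations

- The leading-eigenvector method is greedy recursive bisection; it can
  miss the global optimum on adversarial graphs (the n = 8 exhaustive
  check bounds the gap only at that scale).
- The MCS count statistic is integer-valued and heavily tied; its
  permutation p-values are slightly conservative or anti-conservative
  depending on tie handling (see above), bounded in simulation but not
  analytically.
- ANCOVA assumes homoscedastic normal residuals; no robust or rank-based
  alternative is provided.
- The pipeline computes the group-level partition for segregation from the
  grand-mean network across all subjects (symmetric treatment of groups);
  per-group partitions are reported alongside but not used for the
  segregation contrast.
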