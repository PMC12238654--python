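# Methods

## Model and estimator

The community is treated as a deterministic dynamical system
ż_i = f_i(z) = z_i φ_i(z) over members i = 1..n, where a "member" may be
a bacterial family, a barcode lineage's clonal cluster, or both mixed in
one abundance vector. Taylor expansion around a reference state gives
the community (Jacobian) matrix J_ij = ∂f_i/∂z_j and the per-capita
matrix a_ij = ∂φ_i/∂z_j, related by J = diag(z)A. Viewing a_ij as the
slope of φ_i against z_j, the windowed sample covariance Cov(φ_i, z_j)
is the numerator of that regression slope; the package follows the
convention of reporting the covariance itself as the interaction
strength (so values are scaled by Var(z_j); signs and relative
magnitudes, not absolute units, are the interpretable output).

Assumptions worth stating plainly:

- **Derivative quality bounds everything.** f is estimated by
  three-point Lagrange finite differences on the raw, possibly
  irregular grid (second-order interior, one-sided at the ends; exact
  for quadratics). No smoothing is applied — callers who want smoothing
  feed LOESS consensus curves, as the lineage pipeline does. Sampling
  much coarser than the dynamics' timescale biases f and hence J.
- **Covariance ≠ regression.** Cov(φ_i, z_j) equals (A · Cov z)_ij, so
  the estimate mirrors the true A only where Cov(z) is
  diagonal-dominant. A single smooth relaxation trajectory makes all
  z_k mutually correlated and scrambles off-diagonal signs; an ensemble
  of independent perturbation–relaxation episodes (or rich, jittery
  real data) restores diagonal dominance. The sign-recovery experiment
  in `experiments.py` is built accordingly, and users should not expect
  entrywise sign fidelity from one featureless transient.
- **Expanding windows trade locality for noise suppression.** All
  windows share the first sample; a window's estimate is a cumulative
  summary up to its end time. Events therefore appear at the window
  whose *end* first covers them. The minimum window is 3 samples
  (the derivative needs 3, the covariance 2).

## Stability reading of the spectrum

For each window's J, the local solution is a combination of modes
e^{λt}: max Re λ > 0 flags instability and max |Im λ| > 0 oscillation,
both at a scale-aware tolerance (1e-9 × spectrum norm, so
numerically-zero parts do not flip labels). Eigenvalues are ranked by
magnitude within each window (conjugate pairs: +Im first), not matched
by continuity across windows — rank order is what the downstream PCA
consumes, and an optional greedy matcher was deliberately left out of
the default path to keep the pipeline deterministic and simple. The
identity λ_i = z_i μ_i between the spectra of J = diag(z)A and A holds
exactly only for uniform z (it is tested in that regime); for
heterogeneous z it is a heuristic correspondence.

## Phase detection

The windows × 2N eigenvalue matrix is reduced by kernel PCA (linear
kernel by default — classical PCA; an RBF kernel with median-heuristic
bandwidth is available). Scores are sign-fixed (largest-magnitude score
positive) for determinism. The (PC1, PC2) plane is mapped to two
univariate series — distance from the origin and planar angle in
[0, 2π) — mirroring the geometric-mapping approach to multivariate
changepoint detection. Each series is segmented by exact dynamic
programming under a nonparametric cost: the series' distribution is
summarized at K tail-weighted quantile levels and each segment scored
by binomial log-likelihoods of its empirical exceedance fractions.
Penalties per changepoint: BIC = SIC = p·log T, HQ = p·log log T, and
MBIC = p·log T plus 3/2·log(segment length) per segment, with p = 2.
The default ensemble is 4 penalties × K ∈ {10, 20} × 2 mapped series =
16 runs. Boundaries within ±1 window are merged (medoid kept) and
graded: *** when found under all four penalty criteria, ** when in
≥ 90% of runs, * in ≥ 70%, discarded below. Phases are labelled with
Roman numerals in time order.

Degenerate inputs: a constant series yields no changepoints under every
penalty (all segmentations tie in cost, penalties favor none); an
all-identical eigenvalue matrix yields zero PCs and a single phase.

## Barcode pipeline

- **Length filter** keeps 13–17 nt barcodes (the construct is 15 nt;
  indel artifacts shift lengths).
- **Deletion-neighborhood correction**: barcodes ranked by total count;
  a lower-count barcode within Levenshtein distance ≤ 3 of a
  higher-count centroid (total ≥ 2) merges into the nearest such
  centroid when its count is a plausible error load — at most the
  upper 99.9% Poisson quantile with rate 0.1 × centroid count.
  Candidate pairs come from deletion signatures (all ≤3-deletion
  variants), avoiding all-pairs scans. The greedy pass iterates to a
  fixed point, making correction idempotent by construction; reads are
  re-assigned, never dropped. Barcodes matching no centroid are kept
  as-is (downstream persistence filtering removes ephemeral ones).
- **Diversity**: Hill numbers per timepoint; 0D counts nonzero
  lineages, 1D = exp(Shannon entropy), ∞D = 1/max f. The ordering
  0D ≥ 1D ≥ ∞D is exact.
- **Persistence filter**: nonzero at ≥ 12 timepoints (of an 18-point
  series; both this and the mean threshold are config values) and mean
  frequency ≥ 5e-5, both boundaries inclusive.
- **Clonal clusters**: ΔF_ij = 1 − Pearson(log f_i, log f_j), computed
  pairwise-complete over timepoints where both lineages are nonzero,
  falling back to zero-replaced values (zeros → half the smallest
  positive frequency) when the overlap is < 4 points. UPGMA linkage,
  cut at a threshold chosen where the min-max-normalized cluster-count
  and cluster-separation (minimum distance between LOESS consensus
  curves) curves cross; clusters below 8 members are discarded and the
  rest ranked C1, C2, … by mean member frequency. LOESS uses tricube
  weights, local degree 1, span 0.3 (widened to cover ≥ 3 points on
  very short series).

## Cross-level statistics

Family counts are column-normalized; families with mean fraction
strictly below 1e-3 pool into "Other". For co-clustering, family series
(≥ 7 nonzero timepoints, log-transformed with the same half-minimum
zero rule) and clone consensus curves are z-normalized and compared by
shape-based distance, SBD = 1 − max over integer shifts of the
normalized zero-padded cross-correlation — tolerant of amplitude and
phase differences, bounded in [0, 2]. The joint UPGMA tree's cophenetic
distances feed the mixing index D_cm = 1 − sup|F(c) − F(m)|, where F(c)
and F(m) are the empirical CDFs of clone–clone and clone–family pair
distances; this KS-statistic reading is the package's concretization of
the mixing formula (the quantity compared is tree distance
distributions, and the sup-difference is the only well-typed reading).
Overlap significance draws null set pairs uniformly without replacement
from the barcode pool (1000 replicates by default), reports
Z = (OC − μ)/σ and a two-sided normal p; a degenerate null (σ = 0) is
reported as undefined rather than infinite.

## Synthetic data: what it does and does not emulate

The gLV simulator integrates segment-wise with adaptive Runge–Kutta
(rtol 1e-8), re-initializing at schedule boundaries because a matrix
switch is a discontinuity of the vector field; abundances below 1e-12
are clamped to zero (extinction floor). `make_switch_scenario` draws
off-diagonals uniform in [−1, 1], diagonals in [−1.5, −0.5], growth
rates in [0.5, 1.5], and rejection-samples until each matrix's
symmetric part is negative definite — negative diagonals alone do not
prevent mutualistic blow-up, whereas dissipativity bounds total
abundance at n|r|/c with c the symmetric-part stability margin. The
second matrix must flip at least one off-diagonal sign.

The read simulator draws template molecules multinomially, amplifies
each through per-molecule stochastic doubling (Galton–Watson, which
reproduces PCR jackpot tails), samples reads multinomially from the
amplified pool, and corrupts barcodes base-by-base. It emulates
sampling noise, PCR skew, and sequencing error — not chimeras, context-
dependent error hotspots, primer bias, or real phylogenetic structure.
Tests passing on this generator show the estimators and the correction
logic are right under the stated noise model; they do not certify
performance on real libraries with structured artifacts.

Planted lineage groups use distinct smooth log-frequency templates
(rising/falling/humped) with iid Gaussian log-noise — deliberately
favorable geometry for validating the clustering chain, not a model of
real clonal interference.

## Experiment problem sizes

The switch-localization experiment uses 5 species, grid 0..40 at
Δt = 0.5 (79 windows), 10 replicate seeds, and the default 16-run
changepoint ensemble. The sign-recovery experiment uses 20 random
stable 4-species communities, each probed by 400 perturbation episodes
(±30% around equilibrium) observed at 3 timepoints spaced c × 0.1 for
coarsening factors c ∈ {1, 2, 4, 8}; 400 episodes put the pooled
covariance's sampling noise well below the coarsening-bias signal being
measured. Both finish in seconds to tens of seconds on one CPU.

## Known limitations

- Covariance estimates are unnormalized (units of Var(z_j)); comparing
  strengths across members with very different abundance scales
  requires care, and no sparsity or regularization is applied.
- Expanding windows blur the timing of late events; a sliding-window
  variant is deliberately out of scope.
- Changepoint grading counts a boundary found under all four penalties
  as *** regardless of run support; with 16 runs this is permissive,
  which is why the consensus also reports the support fraction.
- The mixing-index F(·) and several zero-handling rules (log of zero
  frequencies, combined clone+family abundance vectors without
  rescaling) are documented package choices where the underlying
  procedure admits more than one reading.
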