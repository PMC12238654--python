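# dcmkit

Model-free estimation of time-resolved microbial community interaction
matrices from abundance time series, with eigenvalue-based stability
analysis, changepoint-based phase detection, and a toolbox for
chromosomal-barcode lineage tracking (error correction, Hill diversity,
clonal clustering, clone/family co-clustering statistics).

## Who this is for

Microbial ecologists and systems biologists who have member-by-time
abundance tables — 16S family profiles, barcode lineage frequencies, or
both — and want to know how the community's interaction structure and
stability change over time *without* fitting a parametric ecological
model. Typical use cases: gut colonization experiments, perturbation
(antibiotic, invasion) studies, and in-vitro community dynamics.

## The method

A community is described by abundances z_i(t) obeying
ż_i = f_i = z_i φ_i, where f_i is the population growth rate and φ_i the
per-capita rate. Near a reference state, the effect of member j on
member i is the Jacobian entry J_ij = ∂f_i/∂z_j, estimated here
non-parametrically as a dynamic covariance over a time window:

    J_ij(τ) = Cov(f_i, z_j)      (overall interaction strength)
    a_ij(τ) = Cov(φ_i, z_j)      (per-capita interaction strength)

with J = diag(z)·A linking the two. Growth rates come from three-point
finite differences on the (possibly irregular) sampling grid, and the
covariances are computed over *expanding* windows anchored at the first
sample. Each window's eigenvalues λ = θ + iω classify the community as
stable/unstable (sign of θ) and oscillatory (|ω|). Stacking the
magnitude-ranked (Re, Im) eigenvalue components over windows gives an
s × 2N trajectory matrix; kernel PCA reduces it to (PC1, PC2), a
geometric mapping converts that plane to distance and angle series, and
nonparametric (empirical-quantile) changepoint detection under an
ensemble of penalties (MBIC, BIC, SIC, Hannan-Quinn) × quantile
settings yields consensus phase boundaries graded ***, **, *.

The lineage toolbox covers the intra-species side: barcode read-count
cleaning (length filter + deletion-neighborhood error correction with a
Poisson plausibility test), Hill diversity qD = (Σ f^q)^{1/(1−q)} for
q ∈ {0, 1, ∞}, persistence filtering, UPGMA clustering of lineages by
ΔF_ij = 1 − ρ(log f_i, log f_j) with LOESS consensus curves ("clonal
clusters"), shape-based-distance (SBD) co-clustering of clones with
bacterial families, a Kolmogorov–Smirnov-style mixing index D_cm, and
overlap-coefficient significance via a resampled null.

A generalized Lotka–Volterra simulator (piecewise-constant interaction
matrices, optional switch scenarios) and a barcode read simulator
(multinomial sampling, Galton–Watson PCR jackpotting, per-base errors)
generate every input needed to exercise and validate the chain.

## Worked example

`examples/03_phase_detection.py` simulates the 5-species switch
scenario (interaction matrix A1 → A2 at t = 20) and runs the full
chain:

```
eigen-trajectory matrix: 79 windows x 10 columns

consensus boundaries (window -> time, grade, fraction of runs):
  window   6 -> t =   3.5  ***  support 0.75
  window  12 -> t =   6.5  ***  support 1.00
  ...
  window  40 -> t =  20.5  ***  support 0.62
  ...
```

The boundary at t = 20.5 is the detected interaction-matrix switch
(true time 20); earlier boundaries mark the equilibration transient of
the initial conditions, later ones the post-switch collapse and
re-equilibration. Each `examples/*.py` script demonstrates one
capability (simulation, interaction estimates, phases, barcode
correction + diversity, clonal clustering, co-clustering + overlap) and
prints a line explaining what its numbers mean.

A thin CLI mirrors the library:

```sh
dcmkit simulate glv --seed 1 --out traj.tsv
dcmkit spectrum --input traj.tsv --out eig.tsv
dcmkit phases --input eig.tsv --out phases.tsv
dcmkit run --barcodes reads.tsv --taxa families.tsv --seed 1 --out results/
```

## Layout

- `src/dcmkit/glv.py` — gLV + read simulators (synthetic data)
- `src/dcmkit/dcm.py` — growth rates, windows, covariance estimates
- `src/dcmkit/spectral.py` — eigendecomposition, stability, assembly
- `src/dcmkit/changepoint.py`, `phases.py` — kernel PCA, detection, consensus
- `src/dcmkit/barcode_qc.py` — length filter, deletion-correction
- `src/dcmkit/lineage.py` — frequencies, diversity, clonal clusters
- `src/dcmkit/compare.py` — SBD co-clustering, mixing, overlap
- `src/dcmkit/io.py`, `pipeline.py`, `cli.py` — tables, config, orchestration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
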