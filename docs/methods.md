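# Methods

`allosom` compares two conditions of a molecular-dynamics ensemble — for
example the ligand-free ("apo") and ligand-bound ("holo") forms of a
protein–DNA complex — through three complementary lenses: geometry (RMSD
series, essential-dynamics PCA, solvent-accessible surface area),
displacement cross-correlation networks (communities and suboptimal paths),
and a toroidal hexagonal self-organizing map (SOM) trained on monitored
interface distances. This note records the models, the defaults and why
they were chosen, the numerical conventions, and what the synthetic tests
do and do not demonstrate.

## Geometry

**Superposition.** Rigid-body fits are least-squares (Kabsch, via an SVD of
the cross-covariance); the fit set may differ from the measurement set. The
reported RMSD is recomputed from the transformed coordinates rather than
taken from the solver's residual, which keeps the identity fit at machine
precision (~1e-14 Å rather than ~1e-7).

**RMSD series.** Each frame is fitted on a *fit set* and the deviation is
measured on a *calc set* without refitting. With fit set = calc set this is
the ordinary RMSD from a reference frame; with a scaffold fit set and a
mobile calc set it isolates the displacement of a subdomain relative to a
scaffold. The reference is the first production frame of each trajectory
(deviation-from-start reading), not a crystal structure.

**PCA.** The 3N×3N covariance of the selected Cα coordinates is built over
the frames of *all* supplied ensembles pooled (per-condition covariance is
available behind `pooled=False`), after a two-pass iterative fit onto the
evolving mean structure to remove rigid-body contamination. Pooling puts
both conditions in one eigenvector basis, which is what makes "the two
conditions separate along mode 1" a meaningful statement. A `fit=False`
escape hatch skips the superposition for input already expressed in a
common reference frame — all synthetic generators emit such input, and
refitting would partially absorb their planted collective modes (a rigid
fit soaks up any displacement pattern that resembles a net translation or
rotation). The same flag exists on the DCCM (below) and is set in the
synthetic study configs.

**SASA.** Shrake–Rupley with Fibonacci (golden-spiral) sphere sampling;
defaults probe 1.4 Å, 960 points per atom, Bondi-style element radii from
the bundled table (C 1.70, N 1.55, O 1.52, P 1.80, S 1.80 Å). 960 points
put an isolated sphere within 0.05% of the closed form and a two-sphere
overlap within ~0.1% of the spherical-cap formula. Interface burial
(ΔSASA) of a region by a partner is SASA(region, partner deleted) −
SASA(region, full complex); positive values mean burial. Coincident atoms
are an error, not a warning.

## Interface distances

Each monitored distance connects two endpoints: a single named atom, a
charged-group centroid (Arg NH1+NH2+NE, Lys NZ, Glu OE1+OE2, Asp OD1+OD2)
or a DNA phosphate P atom. Centroids are used for salt bridges because the
side-chain charge is delocalized and centroids are robust to rotamer flips.
Distances are evaluated on a regular time grid (default every 100 ps) and
assembled into a frames × D matrix with fixed column order, so features
align across conditions — a requirement for training one SOM on pooled
frames. The shipped template config holds 25 definitions: four named
ARNT–DNA/intramolecular salt bridges (R88–P, R91–P, R101–P, R101–E98) and
21 documented placeholder slots whose chain/residue pairings must be
supplied by the user for a real system. Frames with unresolvable endpoint
atoms abort the run; nothing is imputed.

## Correlation network

The dynamic cross-correlation matrix over a fitted trajectory is

    c_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),

with Δr_i the displacement of site i from its mean position. Per condition,
the DCCM is the element-wise mean of the per-replica DCCMs (not of
concatenated frames, which would pick up spurious correlation from
inter-replica offsets; concatenation is available by computing one DCCM on
a merged ensemble). A site whose variance corresponds to an RMS fluctuation
below 1e-6 Å is reported as frozen by name.

The residue graph keeps an edge wherever |c_ij| exceeds the cutoff
(default 0.5, the conventional protocol value) and assigns the path weight
w = −log|c_ij|, so that minimizing total path weight maximizes the product
of |correlations| along the path. Anti-correlated pairs enter by absolute
value, both for the cutoff and the weight. A raw-|c| and a linear (1−|c|)
scheme are selectable for comparison; raw weights invert shortest-path
semantics and exist only for inspection.

Communities come from Walktrap random-walk agglomeration with walk length
4 on the |c|-weighted graph, cutting the merge sequence at maximum
modularity; modularity is weighted Newman Q = Σ_c (e_cc/m − (d_c/2m)²).
Walktrap is deterministic; the seed parameter exists for interface
symmetry. Suboptimal paths are the k globally shortest simple paths
(default k = 50) pooled over *all* source×sink residue pairs — Yen's
algorithm per pair with a lazy heap merge — rather than one representative
node per set; per-node usage counts over the retained ensemble flag
bottleneck residues. A disconnected source/sink pair yields an explicit
`disconnected` status rather than an error, since losing a communication
route is itself a result.

## Self-organizing map

The SOM is a 10×10 hexagonal lattice with toroidal periodicity (no map
border, six equivalent neighbours per neuron; the row count must be even so
that cyclic row shifts preserve hex adjacency). Lattice distances are
Euclidean distances between hex-offset neuron centers at unit spacing,
minimized over the nine periodic images.

Training is the deterministic *batch* variant: per epoch, every input
vector is assigned to its best-matching unit (BMU, nearest codebook,
ties to the lowest index), then every codebook moves to the
Gaussian-neighbourhood-weighted mean of the data,
h = exp(−d²/2σ²) over toroidal lattice distance. σ decays linearly from
half the maximal lattice distance to 0.5 across epochs (default 100
epochs; 50 in the pipeline config, which converges for these feature
counts). Codebooks are initialized from seeded random draws of input rows.
Training is bit-reproducible given seed and input order. No feature
scaling is applied by default: all 25 inputs share units (Å); a z-score
flag exists. The quantization error is recorded per epoch; on small-radius
plateaus the update is k-means-like and the error decreases monotonically,
while at large radii the algorithm minimizes the neighbourhood-smoothed
distortion instead, so early-epoch increases are expected behaviour.

Neurons are then grouped by complete-linkage agglomerative clustering on
Euclidean codebook distances, with the cluster count chosen by a silhouette
scan (neurons as points, not frames; default range 2–15, ties to the
smallest k; singleton clusters score 0). Per-neuron occupancy is split by
condition; a neuron is *exclusive* to a condition when that condition holds
≥90% of its occupancy and the neuron received ≥10 frames (both thresholds
config-exposed). The per-feature contrast score is the absolute difference
of the feature's mean over the frames in one condition's exclusive neurons
versus the other's; ranking by contrast surfaces the discriminating
features. For display, the torus is unrolled by a pure cyclic re-centering
that places the most populated neuron (ties to the lowest index) at the
grid center, with the row shift rounded to an even amount to preserve hex
adjacency. A richer border-dissimilarity placement rule was deliberately
not implemented: it is under-specified, and cyclic re-centering already
preserves the topology exactly.

## Synthetic generators

The generators produce data with the statistical structure each analysis
assumes, plus the ground truth needed to score recovery. All are Gaussian
displacement models — distributional, not kinetic; no force fields, no
solvent, no attempt to mimic real protein geometry.

* `block_correlated_ensemble`: site displacements drawn per Cartesian axis
  from N(0, σ²C), C a block correlation matrix (intra-block ρ, inter-block
  value, unit diagonal; PSD validated). The 3D-vector DCCM of the output
  equals C in expectation; the sampling error of a correlation estimate at
  F frames is ≈ (1−ρ²)/√F.
* `domain_shift_ensemble`: a static scaffold plus a compact mobile
  subdomain a 15 Å lever arm away; the "apo-like" condition rotates the
  subdomain about an axis through the scaffold centroid, linearly up to the
  requested magnitude across frames; both conditions share isotropic
  thermal noise. Drives the scaffold-fit/subdomain-calc RMSD contrast and
  plants a dominant PCA mode.
* `two_condition_distances`: D independent Gaussian features (default 25,
  σ = 0.4 Å, base mean 10 Å); a planted subset (default 4) differs in mean
  between conditions by `separation`·σ (default 5σ, half above and half
  below the shared mean). A paired point-particle ensemble realizes every
  feature as an actual inter-atom distance, so the distance-extraction
  stage can be tested end-to-end against the generator's matrix.
* `simulate.build_study` combines all three signatures in one on-disk
  study (reference PDB, multi-model PDB trajectories, domain map, distance
  config, run config, ground-truth sidecar): an apo-only progressive 25°
  subdomain rotation, anti-phase scaffold halves (intra-block ρ = 0.8,
  halves at −0.35) whose coupling to the mobile block is 0.65 in holo and
  0 in apo, and the 4-of-25 planted distance features. Anti-phase halves
  are used because a *uniform* common-mode block displacement is nearly a
  rigid translation and would be absorbed by any trajectory fit; the
  anti-phase construction survives superposition, and the planted holo
  coupling is set above the 0.5 edge cutoff so the planted communication
  route is representable in the network at all. Default size: 300 frames
  per replica, 2 replicas per condition, 42 correlation sites and 50
  distance particles — sized so the full study builds and analyzes in a
  few seconds.

What passing these tests shows: the estimators recover planted
distributional structure (correlations, rotations, mean shifts) at the
stated sample sizes, and the pipeline's plumbing (selections, labels,
pooling, feature alignment) is correct end-to-end. What they do not show:
behaviour on real MD data — force-field physics, anharmonicity,
autocorrelated frames (all generator frames are independent), slow
convergence of correlation estimates on microsecond trajectories, or
imperfectly resolvable endpoint atoms.

## Numerical conventions and degenerate inputs

* Superposition requires ≥3 non-collinear fit atoms; collinear or smaller
  sets raise a degenerate-fit error.
* DCCM values are clipped into [−1, 1] after normalization (guards 1e-16
  overshoot); the diagonal is reset to exactly 1 after replica averaging.
* BMU and argmax/argmin tie-breaks always go to the lowest index; chosen-k
  silhouette ties go to the smallest k. These make every ranking
  deterministic.
* An empty correlation network (cutoff too high) is valid and yields
  singleton communities with modularity 0.
* Distances must be positive and finite; a non-increasing timestamp
  sequence, an atom-count mismatch, or NaN features abort with a specific
  error type.
* All seeds are plain integers fed to `numpy.random.default_rng`; every
  stochastic stage of the pipeline derives from the single seed in the run
  config, which the manifest records.

## Pipeline

`run_compare` sequences: load → RMSD (core and subdomain) → pooled PCA →
per-replica DCCM → per-condition average and difference matrix → network,
communities, suboptimal paths per condition → distances → pooled SOM →
neuron clustering, per-condition maps, torus unrolling → manifest. The
protocol defaults are distance stride 100 ps, |c| cutoff 0.5, 50 paths, a
10×10 toroidal hexagonal grid, and a silhouette range that includes k = 8.
One SOM is trained on the pooled conditions (shared neuron identities are
what make per-condition population overlays comparable). Any stage failure
aborts with the stage name; partial outputs stay on disk flagged
`incomplete` in the manifest. Outputs are CSV/JSON/GraphML only.

## Known limitations

* XTC/DCD reading requires MDAnalysis (optional extra); the test suite and
  synthetic studies use multi-model PDB exclusively.
* The hex torus requires an even row count; odd-row grids are supported
  only as flat (non-toroidal) lattices.
* The exclusivity thresholds (90% share, 10 frames) make the contrast
  score undefined when occupancy is very sparse (≲5 frames per neuron on
  average); the score falls back to zeros and the exclusive sets are empty
  rather than guessing.
* Suboptimal-path enumeration cost grows with k and pair count; the lazy
  per-pair merge keeps the default (50 paths) cheap on residue-scale
  graphs but no bound is enforced.
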