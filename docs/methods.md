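# Methods

This note documents the models and procedures implemented in `cadyn`,
the parameters that matter, the numerical choices, and what the
synthetic-data validation does and does not demonstrate.

## Scope and data model

Everything operates on Cα traces: one bead per residue with an author
residue number, a one-letter code, and helix intervals. Internal indexing
is 0-based and contiguous; intervals are half-open; author numbering is
kept only for reporting. Multi-model files contribute only their first
model (the reference dataset is X-ray only). Consecutive Cα–Cα distances
outside 2.5–4.5 Å are treated as chain breaks: recorded, never bridged,
and never counted as backbone-adjacent by downstream models.

Helix assignment uses Cα-only distance criteria in the style of P-SEA:
a window starting at residue i is helical when d(i, i+3) ∈ [4.8, 5.6] Å
and d(i, i+4) ∈ [5.0, 6.5] Å; covered runs shorter than 5 residues are
discarded. This is purely geometric, hence identical for crystallographic
and synthetic input, and invariant under rigid motion.

## Structural alignment

Pairwise alignment is dynamic programming (Needleman–Wunsch with linear
gap penalty 0.3 and free end gaps) over a similarity score, iterated with
superposition: the first pass scores residues by local distance profiles
(|Cα_i − Cα_{i±δ}| for δ up to 10), each later pass superposes on the
current correspondence (Kabsch) and re-scores with 1/(1 + (d_ij/4 Å)²),
until the correspondence is stable (max 20 rounds). Correspondences
shorter than 10 residues are an explicit failure, never a silent
low-RMSD answer.

The multiple alignment is progressive: an average-linkage guide tree over
pairwise alignment distances (1 − score/min-length), merged leaf-to-root.
Each cluster is represented by per-column mean coordinates; merging two
clusters aligns the two representatives with the same pairwise machinery
and interleaves unmatched columns, so established correspondences are
never revised ("once a gap, always a gap"). An aligned-FASTA import path
accepts external alignments (e.g. MUSTANG) for strict reproduction;
column counts of the internal aligner are reported alongside and are not
expected to equal another program's.

Identity for a pair is (identical residues) / (columns where at least one
of the two is non-gap). Matrix summary statistics are computed over the
full matrix including the diagonal, matching how the reference tables
are conventionally produced (R `summary()` of the whole matrix); the
`summary(include_diagonal=False)` variant is available.

RMSD matrices use the Kabsch superposition over the 100%-occupancy
columns. RMSD-kind matrices are clustered directly on their values as
distances; similarity-kind matrices (identity, RMSIP, AMSM) on Euclidean
distances between matrix rows. Complete linkage is the default
everywhere.

## Superposition, ensemble fitting, core finding

`kabsch_fit` computes the optimal proper rotation via SVD
(`scipy.spatial.transform.Rotation.align_vectors`); the reported RMSD is
recomputed from the transformed coordinates because the least-squares
residual returned by the solver cancels catastrophically for
near-congruent inputs (observed floor ~1e-7 vs ~1e-14 recomputed).

Ensemble fitting iterates superposition onto the evolving mean until the
mean moves < 1e-8 Å RMS. The initial reference is the structure with the
smallest summed pairwise RMSD, which makes the converged mean independent
of input order; refits restart from the previous mean, making
convergence a genuine fixed-point property.

Core finding follows the classical iterated-superposition scheme: refit
on the retained positions, score every position by the volume of its
scatter ellipsoid √det(3×3 covariance across structures), remove the
single worst, and stop when every pairwise RMSD over the retained
positions is below the threshold (default 1.0 Å) or a target count is
reached. The volume statistic is one of several defensible choices; a
count-based stop rule is provided so an RMSD-style elimination can be
emulated. If the threshold is unreachable before 4 positions remain, the
best achieved selection is returned with `threshold_met=False`.

Helix axes are the first principal direction of midpoints of consecutive
Cα pairs (midpoints damp the helical wobble); the inter-helix angle uses
the acute convention arccos|û_a·û_b| ∈ [0°, 90°], and the distance is the
minimum distance between the finite axis segments (centroid–centroid
distance is reported alongside, since interactive tools differ in
convention).

## Ensemble PCA

PCA runs on the flattened Cartesian coordinates of the converged
superposed ensemble (equivalent positions only, no mass weighting),
sample covariance with divisor n−1 — divisor choice cancels in every
variance *fraction*. Implementation is `sklearn.decomposition.PCA` with
the full SVD solver; tests verify its spectrum against an independently
assembled covariance matrix diagonalized with `eigh`. Loadings are
reported per residue as the norm of the (x, y, z) weight triple; a
component with (near-)zero eigenvalue yields a zero profile and a
warning rather than noise.

## Elastic network model

The network connects every residue pair; the default force field is the
distance-dependent Cα parameterization used by the standard NMA
toolchains: with r clamped below at 2.9 Å,

* k(r) = 8.6·10² · r − 2.39·10³  for r < 4 Å (in practice the
  backbone-adjacent pairs at ~3.8 Å),
* k(r) = 128·10⁴ · r⁻⁶           otherwise,

in arbitrary consistent units, unit masses. The switch is on distance,
not sequence separation — at backbone geometry the two coincide, and the
distance form is what the reference R implementation (bio3d) computes;
the test suite cross-checks eigenvalues and fluctuation profiles against
bio3d run through Rscript on a synthetic bundle (agreement is bounded at
~2e-3 relative by the 3-decimal PDB coordinate format). A uniform-cutoff
ANM (k = 1, cutoff 15 Å) is available as a cross-check variant.

The Hessian is assembled from 3×3 super-elements −k/r²·(r⊗r) with
diagonal blocks enforcing exact translational invariance. Springs weaker
than 1e-6 are dropped; the spring graph must be connected (disconnection
is an error naming the components). Eigenvalues below 1e-6 × the largest
are removed as rigid-body modes; any count other than 6 triggers a
warning (chain breaks, collinear degeneracies).

Derived quantities, all over the non-trivial modes unless a subset is
given:

* **Fluctuations** fᵢ = Σₘ ‖vᵢₘ‖²/λₘ, identical to the 3×3-block traces
  of the Hessian pseudoinverse (tested to 1e-6 relative).
* **Deformation energy**: each spring's ½k(Δlength along the mode)² is
  split equally between its endpoints; modes are taken at thermal
  amplitude (∝ 1/√λ), averaged, then min-max normalized to [0, 1] per
  structure. The absolute scale is meaningless by construction; only the
  profile shape is interpreted. Rigid displacement fields give
  identically zero. (Min-max is the default normalization; a z-score
  variant is a keyword away.)
* **Cross-correlations** C_ij = Σₘ(vᵢₘ·vⱼₘ)/λₘ, normalized by the
  diagonal; detects common translation only.
* **RMSIP** over the n = 10 lowest modes (non-trivial, as the toolchains
  remove trivial modes before counting); mode vectors are restricted to
  the aligned residues and re-normalized to unit length without
  re-imposing orthogonality. As a consequence RMSIP is exactly 1 for a
  structure against itself under the identity mapping, and can exceed 1
  marginally for pathological partial mappings; matrix diagonals are
  pinned to 1.

## Dynamic domains (AMSM)

Mode ensembles sample sinusoidal displacements along each of the 5
lowest modes (8 deterministic frames per mode, 40 frames total,
amplitudes ∝ 1/√λ scaled so the softest mode moves 2 Å); phases sum to
zero so the frame mean is the input structure.

The atomic movement similarity for a residue pair compares their
centred across-frame trajectories under the best proper rotation
(batched 3×3 SVD). Two complementary residual mappings are taken and
the larger kept:

* **absolute**: exp(−RMSD/σ), σ = median RMS trajectory displacement —
  groups residues moving in lockstep and residues sharing quiescence;
* **shape**: trajectories normalized to unit size first, residual mapped
  through exp(−d/0.5) — groups residues co-rotating about a common axis
  at different radii, which no magnitude-based comparison can.

The absolute mapping alone mislabels co-rotation (a rigid rotating body
would not score as one domain); the shape mapping alone dissolves a
quiescent domain into noise. The max of the two satisfies all the
designed invariants: a rigidly moving ensemble scores ≥ 0.99 everywhere,
mirrored translations score as co-moving (rotation-compensable — the
property that distinguishes AMSM from cross-correlation), and a global
rigid motion of all frames changes nothing. One caveat follows directly:
for *collinear anti-phase* translations AMSM intentionally reports
co-movement while cross-correlation reports −1, so the two analyses
agree on translation-only motion only when the translation paths have
genuinely different shapes.

Domains are k-medoids on 1 − AMSM (farthest-point initialization from
the most central residue, Voronoi iteration, deterministic given the
seed). `k="auto"` scans k ∈ {2..6} for the best quality score (mean
within-domain minus mean between-domain similarity), ties toward smaller
k, and returns a single domain when no split beats 0.01 — an
uninformative all-ones matrix therefore yields k = 1.

## Pipeline

`run_comparative` executes alignment → identity/RMSD matrices +
clusterings → superposed ensemble → core + helix geometry → PCA →
per-structure modes + profiles → RMSIP clustermap (with Fowlkes–Mallows
agreement between the RMSD and RMSIP two-cluster cuts) → per-structure
AMSM + domains. Per-structure failures in the dynamics stages are
recorded and skipped; alignment failures are fatal. All outputs are CSV
/ Newick / FASTA / JSON; the manifest records coordinate hashes and the
seed, and identical config + seed reproduces every file bit-identically.

The apo/holo comparison maps residues by shared author numbering
(validated by ≥ 80% sequence agreement), falling back to the structural
aligner for renumbered constructs, and reports the Kabsch RMSD over the
correspondence plus per-form profiles, cross-correlation matrices, and
holo − apo difference profiles.

## Synthetic data: what it emulates, what it does not

The generator produces α-helix bundles from canonical helix geometry
(rise 1.5 Å, twist 100°, radius 2.3 Å), placed on a ring with
alternating direction and small random tilt, joined by cubic-Hermite
linkers resampled at ~3.8 Å arc spacing (with a circular-arc fallback
when the Hermite curve would violate Cα spacing limits). Default totals
are drawn from 115–142 residues, matching the size range of the protein
family the pipeline targets. Sequences are poly-alanine with optional
planted cysteines; noise is isotropic Gaussian per atom. Families with
conserved cores plant two noise scales; hinge ensembles rotate one
internally rigid domain about a fixed axis.

These fixtures validate the *mechanics* of every stage against known
ground truth. They do not emulate real crystallographic error models,
side-chain packing, sequence divergence, alternate conformations, or
crystal contacts — so passing tests demonstrate correctness of the
computations, not that biological conclusions transfer to any particular
real family. The real-data stages (reference OBP dataset) run the
identical code paths once the public coordinate files are fetched.

## Problem sizes and determinism

Test and acceptance runs use 4–10 structures of 115–142 residues,
25–40-frame ensembles, and full mode spectra (3N−6 ≤ 420 modes); these
sizes make every check exact rather than sampled, and a full suite run
completes in well under a minute. All stochastic components flow from
explicit integer seeds through `numpy.random.default_rng`; there is no
hidden global state, and every generator is bit-reproducible for a fixed
seed.
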