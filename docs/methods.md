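# Methods

This note documents the models, numerical choices and limitations of
`hippaxes`, module by module.

## Diffusion microstructure (Watson-NODDI and DTI)

The three-compartment model treats each voxel's normalised signal as

    E(b, g) = f_iso E_iso + f_ec E_ec + f_ic E_ic,   f_iso + f_ec + f_ic = 1.

- `E_iso = exp(−b d_iso)` with `d_iso = 3.0×10⁻³ mm²/s` (free water).
- The intra-cellular compartment is a stick (`exp(−b d_par (g·n)²)`)
  averaged over neurite orientations `n ~ Watson(μ, κ)`.
- The extra-cellular compartment is a zeppelin with axial `d_par` and
  radial `d_perp = d_par (1 − ν_ic)`, `ν_ic = f_ic/(f_ic + f_ec)` (the
  classic tortuosity rule on the tissue-relative intra fraction).  The
  *tensor* is Watson-averaged — its axial/radial diffusivities are
  interpolated through τ(κ) = E[(n·μ)²] — and the signal is then Gaussian.
  The alternative (averaging the signal rather than the tensor) is a
  different model; we follow the original NODDI convention.
- `d_par = 1.1×10⁻³ mm²/s`, the grey-matter-optimised value, not the
  white-matter 1.7×10⁻³.

**Watson integrals.**  Both the dispersed-stick signal and τ(κ) reduce to
1-D integrals of `exp(κt²)` against polynomials on [−1, 1].  We expand the
stick kernel and the Watson density in even Legendre polynomials (orders
0–24) with fixed 128-point Gauss–Legendre quadrature for the moments; by
Funk–Hecke the signal is then a short cosine-series in `g·μ`.  Against a
20,000-point spherical quadrature the worst-case error is ~5×10⁻⁷ for
κ ≤ 200 at b ≤ 3000 s/mm², far below the 10⁻³ oracle tolerance enforced in
the tests.  The series is deterministic and fast (~20 μs per evaluation),
which is what makes voxel-wise fitting practical on one CPU.

**Fitting.**  Bounded nonlinear least squares on the normalised magnitudes
(ordinary LS; no Rician likelihood) over (f_iso, ν_ic, κ, μ), with
fractions through logistic transforms, κ through a log transform
(clipped to [10⁻⁶, 10⁴]), and μ in spherical angles.  Initialisation scans
a coarse 4×4×4 grid over (f_iso, ν_ic, ODI) with μ seeded from the DTI
principal eigenvector; the refinement is Levenberg–Marquardt.  There is no
randomness anywhere in the fit.  Noiseless 3-shell recovery is exact to
numerical precision; at SNR 30 the median f_ic error is well under 0.05.

**DTI** uses only b=0 and b≈1000 volumes (≥ 6 unique directions required),
an unweighted log-linear fit of the 6 tensor elements + ln S0, and clamps
negative eigenvalues to zero with a flag.

## Laplace axis fields

Each axis potential solves the 6-connected finite-difference Laplace
equation on the masked voxels, Dirichlet 0/1 on the source/sink voxel sets
and reflecting (no-flux) conditions on the remaining mask boundary; the
sparse system is solved directly and the residual verified against the
tolerance (default 10⁻⁶ on the max residual, far below any downstream
angular sensitivity).  Gradients are central differences (one-sided at mask
edges) in physical mm, then unit-normalised; voxels with gradient magnitude
< 10⁻¹² are flagged invalid and excluded downstream rather than imputed.

Limitation: with piecewise-constant Dirichlet boundaries on a curved
(voxelised) domain, the field in the first free layer next to a boundary
ring inherits a staircase artifact.  On the half-cylindrical shell fixture
the interior IO field is within 2–3° (median) of the analytic radial
direction, but worst-case voxels adjacent to the rings reach ~11°, and ring
voxels themselves (one-sided differences into a constant set) are worse.
Downstream cosine-similarity maps therefore exclude invalid voxels, and
tests assert distributional bounds rather than a uniform worst case.

## Orientation coherence

Cosine similarity is `|a·u|/(|a||u|)` per voxel — scale-invariant,
symmetric, antipodally symmetric, in [0, 1].  Voxels with failed NODDI fits
or flat Laplace gradients propagate as invalid.  The three axis fields are
treated independently (they are only exactly orthonormal on a slab).

## Surface sampling and averaging

For each midthickness vertex, the local prism is spanned by the
unfolded-grid tangent steps and the inner→outer vector.  The prism is
filled with a dense deterministic point grid (default 5×5×12 points along
the two tangents and the normal); each voxel's weight is the prism points
it contains times a Gaussian in signed distance from the midthickness
sheet with σ = thickness/2 (configurable; the mapping of thickness to σ is
a design choice, not a claim of equivalence with any particular toolbox).
Algebraically this equals a per-point Gaussian-weighted average of the
voxel values at the prism points.  Sampling the prism rather than
supersampling the voxels keeps the overlap estimate well-defined when
vertices are spaced more finely than the voxel grid (sub-voxel prisms
would otherwise miss every voxel-side sample).  Weights are renormalised;
zero-weight vertices are missing (NaN), and missingness propagates through
group averaging as NaN, never as zero.  Sampling is linear in the volume
and bounded by the in-ribbon value range.

## Torus spin test

Unfolded maps live on a rows×cols grid treated as periodic.  The null for a
Spearman correlation permutes one map by a random torus isometry — a cyclic
(dr, dc) shift, composed with a 180° rotation with probability ½ — which
preserves neighbour structure and hence spatial autocorrelation exactly
(the lag-1 Moran statistic is invariant, asserted in tests).  The identity
transform is excluded and resampled; p is two-sided with the +1 correction,
so the smallest attainable p is 1/(n_perm+1).  Continuous (interpolated)
shifts and other rotations are not in the transform group; this discrete
group is the set of exact isometries of a rectangular torus grid.  FDR
correction (Benjamini–Hochberg, via statsmodels) is applied jointly across
all map pairs of a report.  Calibration on independent smooth map pairs
gives a type-I error within [0.03, 0.08] at α = 0.05 with 500 permutations,
and power > 0.9 for planted ρ = 0.9.

## OPNNMF

The input matrix X (vertices × subject-metrics) is normalised by z-scoring
each metric within a hemisphere (pooling vertices and subjects) and then
shifting every value by the single global minimum, making X ≥ 0 with
minimum exactly 0.  C is initialised by non-negative double SVD (exact
zeros floored at a tiny positive value so multiplicative updates can move
them) and refined by the Yang–Oja update

    C ← C ⊙ (XXᵀC) ⊘ (C CᵀXXᵀC)          (denominator floored at 10⁻¹²).

The raw update is not scale-stable — the overall norm of C oscillates in a
2-cycle — so after each update C is rescaled by the global factor that
minimises ‖X − CCᵀX‖²; the objective is monitored at that scale and
iteration stops when its relative change falls below 10⁻⁵ (default; max
10,000 iterations).  C is returned at the objective-optimal global scale:
we deliberately do **not** rescale columns to unit norm at exit, because
the converged Gram matrix CᵀC is close to, but not exactly, a multiple of
the identity, and per-column rescaling measurably inflates reconstruction
error and can break the monotone decrease of error across k.  The
orthogonality residual ‖CᵀC − I‖ is reported, not enforced.  Dead
components are re-seeded once from the largest-residual vertex.

Winner-take-all labels are the per-row argmax of C (ties to the lowest
index; all-zero rows flagged).  W = CᵀX; for display W is z-scored within
each component row.

**Stability.**  Subjects (all metrics and hemispheres of a subject travel
together) are split into equal halves n_splits times; OPNNMF is fitted per
half; each half's vertex×vertex cosine-similarity matrix S = ĈĈᵀ uses the
row-normalised Ĉ (a true cosine similarity); matched rows of the two S
matrices are Pearson-correlated, and the coefficients pooled over vertices
and splits.  Identical halves give exactly 1.  The statistic is invariant
to component permutation and sign by construction.

## Subfield classifier

Multinomial logistic regression with L2 penalty (strength 1/C, C = 1.0 —
the regularisation is a library default, not a tuned value) on features
standardised with training statistics (the penalty is scale-sensitive).
Splits are at the subject level with hemispheres grouped.  The confusion
matrix and per-class precision/recall/F1 are computed in-package
(F1 defined as 0 when precision + recall = 0) and cross-checked against
scikit-learn in the tests.  A DTI-variant feature set (FA, MD, T1w/T2w) is
available for the NODDI-vs-DTI separability comparison.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (arguments, seed).

- **Voxel domains**: a full-box slab (axis boundary pairs are orthogonal
  faces) and a half-cylindrical curved shell (bend radius default 8 voxels)
  whose axis fields are non-trivially oriented.  Real hippocampal geometry
  (folding, per-subject shape) is not emulated.
- **Diffusion signals** come from the same forward model family the fit
  assumes (verified against an independent quadrature oracle), with
  Gaussian noise of scale mean(b0)/SNR by default; Rician noise is
  available.  The noise model of any particular scanner/toolchain is not
  claimed.  Recovery tests on these signals show self-consistency of the
  fit, not robustness to model misspecification.
- **Unfolded stacks**: default 64×32 = 2048 vertices at ~1 mm spacing
  (close to the 2004-vertex real surfaces they stand in for), k planted
  torus-Voronoi parcels with non-negative subject-metric loadings plus
  smooth noise (Gaussian-filtered white noise with periodic wrap,
  σ = 2 px default — consistent with the torus assumption of the spin
  test).  Real maps have boundary effects and anatomically structured
  covariance the generator does not produce.
- **Subfield tables**: Gaussian draws around grey-matter-plausible class
  means for (ODI, NDI, T1w/T2w); defaults give moderately separable
  classes.  Passing classifier tests demonstrates the scoring machinery,
  not real-data separability.

The demo pipeline shares one voxel domain across synthetic subjects
(subject variation enters through per-voxel ground-truth perturbations);
per-subject native geometry is out of scope.

## Problem sizes

Default demo/pipeline sizes were chosen so the full synthetic study runs
comfortably on a single CPU: 8 subjects, a 10×8×8 voxel domain, a 32×16
unfolded grid, a 6+3×30-volume scheme, 500 spin permutations, k-sweep 2–6
with 2 splits.  All are configurable; the statistical calibration suites
use 400 null pairs (type I) and 100 planted pairs (power).
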