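# Methods

## Model

The method assumes that, at the scale of one voxel and its immediate
neighbors, the boundary of a compact structure is locally polyhedral: a
face (one plane), an edge (two intersecting planes), or a vertex (three).
Each such local geometry is represented by a binary **edge unit** — a
6×6×6 pattern at twice the native resolution, formed by intersecting
half-spaces, with 1 inside the structure and 0 outside — and by its 3×3×3
block-mean downsample, which is what real data is compared against.
Intensity is modelled as affine in the unit: `I ≈ K·E + B`, so arbitrary
contrast, brightness offset, and polarity (bright-on-dark or dark-on-bright,
via the sign of K) are absorbed by the fit and no intensity normalization
is needed. The model deliberately carries no texture: it recovers the
*boundary* of a homogeneous blob, not internal lamination or fine detail.

## Library construction

One-plane units are enumerated by sweeping planes through the unit cube:
a voxel is 1 iff its center lies in the closed half-space, which by the
central symmetry of a cubic voxel equals the "at least half the voxel
covered" rule. Orientations come in nested tiers (`angular_density`):
coordinate axes (0), + face diagonals (1), + body diagonals (2), +
Fibonacci-sphere points (≥3); signed offsets are sampled at quarter-
low-res-voxel spacing, which resolves every half-voxel plane position
representable on the doubled output grid. Nesting makes the enumerable
pattern set grow monotonically with density. There is no natural plateau:
the number of distinct half-space binarizations of 216 voxel centers is of
order 10⁵, so the density is an explicit resolution/cost parameter rather
than something to be saturated.

Two-plane units are all pairwise products (intersections) of one-plane
patterns; three-plane units are products of one-plane with retained
two-plane patterns. Products whose binary pattern has standard deviation
below `sd_cutoff` (default 0.19, i.e. variance < 0.0361, i.e. fewer than
~9 or more than ~207 of 216 voxels set) are excluded: these are slivers at
the very periphery of the cube that carry almost no edge signal but would
otherwise dominate the library combinatorially. The cutoff is deliberately
permissive enough to keep the *central* edge and vertex units (the
quarter-slab with p = 0.25 and the octant with p = 0.125): without them a
cube's edges and corners cannot be reconstructed exactly, and the
noiseless phantom demonstrably fails to snap to the true mask.

Patterns are deduplicated **up to complement** and ordered by
(n_planes, 216-bit pattern key). The complement of a unit is affinely
indistinguishable from it (K → −K), so keeping both would make every
minimum-SSR selection an exact tie between two representatives and the
selection nondeterministic at rounding level. The fixed ordering puts
1-plane units first, which matters for tie-breaking (below).

## Fitting and selection

The closed forms K = Σ E·(I−⟨I⟩)/Σ E·(E−⟨E⟩), B = ⟨I⟩ − K·⟨E⟩ minimize
SSR = Σ(I − K·E − B)², and SSR = S_II − K·S_EI. Minimizing SSR over units
is equivalent to maximizing the matched-filter score
|S_EI|/√S_EE, which the vectorized path evaluates for all units at once
(float32 BLAS for preselection, float64 for the final decision, so the
fast path agrees with the exhaustive float64 reference).

**Tie handling.** Exact ties are structural, not exceptional: a flat
neighborhood is fitted perfectly by *every* unit (K = 0), and a
low-information neighborhood (e.g. a single partial-volume face layer) is
fitted perfectly by many geometrically different units whose downsamples
agree affinely on that data. Comparing floating-point SSRs exactly would
let last-ulp rounding pick among mathematically tied candidates — in
practice selecting, e.g., a diagonal-stripe slab instead of a face plane
and corrupting the reconstruction. All fits whose score is within a
relative band (`tie_rel`, default 1e-2) of the best are therefore treated
as tied and the lowest unit index wins, preferring 1-plane over 2- over
3-plane geometry. The band also acts as a mild simplicity prior under
noise; reconstruction quality across σ was the criterion for its default.

## Substitution, averaging, iteration

Each voxel is replaced by the central 2×2×2 block of the winning unit's
high-resolution pattern, scaled by (K, B): output dims double, voxel size
halves, and the affine preserves world coordinates. One detection pass is
followed by signal averaging: the high-resolution image is partitioned
into 2×2×2 cells on a grid shifted by one high-resolution voxel and
cell-averaged back to native resolution. The shift makes every averaging
cell straddle eight neighboring substitution blocks, so independent noise
is averaged down while plane positions — representable at any half-voxel
offset in the library — are preserved; images composed exactly of library
planes are fixed points of the detect→average→detect cycle. The shift
alternates (+1,+1,+1)/(−1,−1,−1) between iterations so the net drift
cancels over pairs; any residual half-voxel shift after an even number of
averaging steps is recorded in the output affine (never resampled away).
Intermediate results stay in double precision throughout. Borders are
handled by edge replication, both for 3×3×3 neighborhoods and for shifted
averaging cells; replication adds no invented gradients at the ROI faces.

Defaults: 3 iterations for anatomical volumes, 6 for noisy phantom work.

## Phantom validation

The generator rasterizes a cube of edge 5.6 mm (7 voxels at 0.8 mm) into a
22³ ROI by exact per-axis overlap fractions, so the rasterized volume is
5.6³ = 175.616 mm³ to machine precision for any placement. The default
half-voxel offset puts every face on voxel centers: the cube spans 8
layers per axis with 8³ − 6³ = 296 strictly fractional voxels — the
worst-case partial-volume configuration. On the doubled grid the same
offset is exactly one high-resolution voxel, so the ground-truth mask is
grid-aligned and binary (14³ = 2744 voxels); truth masks are rasterized
directly on each output's own grid, honoring any recorded averaging shift.

Gaussian noise (σ in contrast units; the contrast is 1, so σ = 1/16 … 1
means CNR 16 … 1) is added globally, i.i.d., from a seeded generator; a
master seed spawns independent per-replicate streams and each replicate's
seed is recorded in the results table. Enhanced outputs are segmented
automatically: threshold at background + contrast/2 (polarity-aware), keep
the largest 26-connected component. The "0 iterations" condition is the
unprocessed noisy image block-replicated onto the high-resolution grid so
all Dice comparisons share one grid.

The validation library is the axis-aligned tier (density 0: 15/318/1320
units). The phantom is axis-aligned, so this library represents its
geometry exactly; measured on the σ = 1/2 protocol, a ~70× larger
mixed-orientation library *lowers* Dice by ~8 points, because a larger
template dictionary fits more structure into pure noise (overfitting), and
costs proportionally more time. For real anatomy, whose surfaces are
oblique, the tool defaults to density 1 (axis + face diagonals).

Problem sizes used by the shipped experiments: noise sweep with 5
replicates per σ at 6 iterations; convergence with 3 replicates each at
6/12/18/24 iterations (snapshots of a single 24-iteration run, which is
identical to separate runs because the offset schedule is deterministic).

## What the phantom does and does not show

Passing phantom tests establishes: exact partial-volume arithmetic;
noiseless recovery that is exact and iteration-invariant; volume and shape
recovery within a few percent down to CNR 2; graceful degradation at
CNR 1; and absence of accumulating shape distortion over 24 iterations.
It does not establish performance on real tissue: the phantom is a
homogeneous axis-aligned cube with stationary Gaussian noise, while real
LGN boundaries are curved and oblique, intensity is inhomogeneous, and
noise is spatially correlated. Published human-rater results for this
class of method (volumes ~175 ± 8 mm³, inter-rater ICC ~0.74–0.81) depend
on rater behavior and MRI data that an automated phantom cannot emulate.
One measurable consequence: the automated half-max segmentation keeps
improving with iterations (pooled DSC deficit ~3.5% over 6–24 iterations
at σ = 1/2), whereas human raters plateau near 4.4% — the automated
surrogate is *more* consistent than the raters it replaces, so
rater-anchored reference values are matched only within the replicate
spread, not exactly.

## Numerical choices

- All fits in float64; float32 used only to preselect candidates, with a
  margin (1e-4 relative) far exceeding float32 rounding so the float64
  decision set is never truncated.
- Tie band 1e-2 relative on the matched-filter score; lowest index wins;
  an exactly-flat neighborhood resolves to unit 0 and reconstructs the
  constant exactly regardless of the representative chosen.
- Degenerate unit (zero centered energy) falls back to K = 0, B = ⟨I⟩;
  valid libraries never contain such units.
- Segmentation threshold uses ≥ (half-maximum kept), so noiseless
  half-filled face voxels on the native grid are included deterministically.
- Volume conservation, block-mean conservation, polarity antisymmetry
  (enhance(−v) = −enhance(v) bit-exactly), and world-coordinate
  preservation are enforced by property tests.

## Known limitations

- Vertices of more than three planes are not modelled; heavily non-convex
  or high-curvature geometry falls back to the nearest polyhedral fit.
- The library's published reference cardinalities (109/768/34048) arise
  from an unspecified enumeration scheme and are not reproduced; counts
  here are a function of the documented sampling tiers and are logged for
  comparison only.
- Whole-brain processing is out of scope; the tool operates on seed-
  centered ROIs (configurable size) and assumes isotropic voxels.
- The automated segmentation is a half-max rule, not a rater model;
  DSC/volume figures at high noise are not directly comparable to manual
  delineations beyond the tolerances discussed above.
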