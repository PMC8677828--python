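# edgeup

Edge-enhancing 2× upsampling of small, low-contrast structures in 3D MRI,
with a cube-phantom framework for validating volume and shape recovery.

## The problem

Small subcortical structures — the lateral geniculate nucleus (LGN) is the
motivating example — span only a handful of voxels in a routine 0.8 mm
T1-MPRAGE scan. Their boundary voxels mix structure and surround
(the partial volume effect), so a manual delineation is uncertain by the
entire boundary shell. For a 7×7×7-voxel cube placed off-grid by half a
voxel, every face is partial-volume: depending on how the 296 fractional
voxels are counted, the measured volume lands anywhere between
110.6 mm³ and 262.1 mm³ around a true 175.6 mm³.

## The method

Local surface geometry is modelled as the face, edge, or vertex of a
polyhedron: a binary 6×6×6 **edge unit** E formed by 1–3 intersecting
half-spaces, paired with its 3×3×3 block-mean downsample. For every image
voxel, the 3×3×3 neighborhood *I* is fitted affinely against every
downsampled unit in a precomputed library,

```
I ≈ K·E + B
K   = Σ E·(I−⟨I⟩) / Σ E·(E−⟨E⟩)
B   = ⟨I⟩ − K·⟨E⟩
SSR = Σ (I − K·E − B)²
```

and the minimum-SSR unit (equivalently, the maximum of the matched-filter
score |Σ E·(I−⟨I⟩)| / √(Σ E·(E−⟨E⟩))) defines the local geometry. The voxel
is replaced by the central 2×2×2 block of that unit's high-resolution
pattern, scaled by (K, B) — doubling resolution from 0.8 to 0.4 mm and
snapping boundaries onto fitted planes. Detection alternates with signal
averaging on a 2×2×2 grid shifted by one high-resolution voxel, which
suppresses noise without displacing the detected surfaces; the two-step
cycle is iterated (3 iterations for clean anatomy, 6 for noisy data).

Accuracy is validated on a synthetic cube phantom (contrast 1, additive
Gaussian noise σ = 1/16 … 1, i.e. CNR 16 … 1): enhance, segment at
half-maximum with largest-connected-component selection, then score the
recovered volume and the Dice similarity coefficient
`DSC = 2·V_shared / (V_cube + V_delineation)` against the exact
high-resolution cube mask.

## Worked example

```python
from edgeup import (GenerationConfig, NoiseSpec, PhantomSpec, add_gaussian_noise,
                    build_library, enhance, rasterize_cube)
from edgeup.phantom import evaluate

lib = build_library(GenerationConfig(angular_density=0))
print(f"library units by n_planes: {lib.counts_by_nplanes} (total {len(lib)})")

spec = PhantomSpec()                      # 5.6 mm cube, half-voxel offset, 22^3 ROI
noisy = add_gaussian_noise(rasterize_cube(spec), NoiseSpec(sigma=0.5, seed=11))
out = enhance(noisy, lib, n_iterations=6)
m = evaluate(out, spec)
print(f"output grid: {out.shape} at {out.voxel_size_mm:.1f} mm")
print(f"recovered volume: {m.volume_mm3:.1f} mm^3 (truth {m.truth_volume_mm3:.3f})")
print(f"Dice coefficient: {m.dsc:.3f}")
```

prints

```
library units by n_planes: {1: 15, 2: 318, 3: 1320} (total 1653)
output grid: (44, 44, 44) at 0.4 mm
recovered volume: 175.7 mm^3 (truth 175.616)
Dice coefficient: 0.957
```

At CNR 2 (σ = 0.5) the enhanced, automatically segmented cube recovers its
volume to well within the partial-volume uncertainty band and its shape to
DSC ≈ 0.95; the same half-max segmentation applied to the unprocessed noisy
image returns several times the true volume. With σ = 0 the recovery is
exact (DSC = 1, volume 175.616 mm³) and invariant under further iterations.

## Command line

```
edgeup build-library --out lib.h5 --angular-density 1
edgeup enhance --in T1.nii.gz --center 92,110,85 --roi 22 \
               --library lib.h5 --iterations 3 --out lgn_enh.nii.gz
edgeup phantom-validate --library lib.h5 --sigmas 0.0625,0.125,0.25,0.5,1 \
               --iterations 0,1,3,6 --replicates 5 --seed 17 --out results/
edgeup metrics --truth truth.nii.gz --delineation seg.nii.gz
```

`enhance` extracts a 22³ ROI around the seed voxel (locate it visually,
e.g. in ITK-SNAP), runs the iteration, and writes a 44³ NIfTI at 0.4 mm
whose world coordinates overlay the source scan. `phantom-validate` writes
per-replicate and summary CSVs of the noise sweep.

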