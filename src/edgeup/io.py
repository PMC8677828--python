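"""NIfTI I/O and seed-centered ROI extraction.

The enhancement operates on a small region of interest (default 22^3
voxels) extracted around a user-supplied seed coordinate -- the structure
of interest is located visually (e.g. in ITK-SNAP) and its approximate
center passed in voxel coordinates.  World geometry is carried through
extraction and enhancement in the affine, so the written output overlays
the source scan correctly at double resolution.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import nibabel as nib
import numpy as np

from .enhance import VolumeGrid

__all__ = ["RoiSpec", "read_volume", "write_volume", "write_enhanced", "extract_roi"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class RoiSpec:
    """Seed-centered region of interest, in 0-based voxel coordinates."""

    center_vox: tuple[int, int, int]
    dims: tuple[int, int, int] = (22, 22, 22)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_vox, dtype=int)
        d = np.asarray(self.dims, dtype=int)
        start = c - d // 2
        return start, start + d


def read_volume(path: str) -> VolumeGrid:
    """Load a 3D NIfTI volume with voxel size and world affine.

    Anisotropic voxels are accepted with a warning (the method assumes
    isotropic resolution); 4D images are rejected.
    """
    img = nib.load(path)
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
        shape = img.shape
    if len(shape) != 4 and len(shape) != 3:
        raise ValueError(f"expected a 3D image, got shape {shape}: {path}")
    if len(shape) == 4:
        raise ValueError(
            f"4D time series are not supported (method operates on one 3D "
            f"anatomical volume); got shape {shape}: {path}"
        )
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        warnings.warn(
            f"anisotropic voxels {tuple(zooms)} in {path}; the method assumes "
            "isotropic resolution",
            stacklevel=2,
        )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return VolumeGrid(
        data=data,
        voxel_size_mm=float(zooms[0]),
        affine=np.asarray(img.affine, dtype=np.float64),
        resolution_level="low",
    )


def write_volume(vol: VolumeGrid, path: str) -> None:
    """Write a VolumeGrid as NIfTI-1, voxel size taken from the affine."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms((vol.voxel_size_mm,) * 3)
    nib.save(img, path)


def write_enhanced(vol: VolumeGrid, path: str) -> None:
    """Write an enhanced (high-resolution) volume; sanity-checks the level."""
    if vol.resolution_level != "high":
        raise ValueError("write_enhanced expects a high-resolution output volume")
    write_volume(vol, path)


def extract_roi(vol: VolumeGrid, roi: RoiSpec) -> VolumeGrid:
    """Sub-volume around the seed with world coordinates preserved.

    Out-of-bounds ROIs raise (no silent clamping): the structure must be
    contained in the ROI in its entirety, so a clipped box would be wrong.
    """
    start, end = roi.bounds()
    shape = np.asarray(vol.shape)
    if (start < 0).any() or (end > shape).any():
        raise ValueError(
            f"ROI {tuple(roi.dims)} centered at {tuple(roi.center_vox)} exceeds "
            f"image bounds {tuple(shape)}"
        )
    sub = vol.data[start[0]:end[0], start[1]:end[1], start[2]:end[2]].copy()
    shift = np.eye(4)
    shift[:3, 3] = start
    logger.info(
        "extracted ROI %s at %s (%d voxels)",
        tuple(roi.dims), tuple(start), sub.size,
    )
    return VolumeGrid(
        data=sub,
        voxel_size_mm=vol.voxel_size_mm,
        affine=vol.affine @ shift,
        resolution_level="low",
    )
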