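"""Voxel-lattice tissue model: density calibration, segmentation, regions, 3D I/O.

The simulation operates on an isotropic 3D voxel lattice (default edge length
10.5 um, micro-CT resolution).  Each voxel carries a grayscale bone density
(linear map of 0--1,160 mg HA/cm^3 onto [0, 1]), continuous mineral and
osteoid concentrations ``m, o in [0, 1]``, and a categorical region label.
The binary "bone phase" used for finite-element material assignment and for
cell placement is the segmentation of the grayscale at 0.5 (i.e. 580 mg
HA/cm^3); mineral and osteoid stay continuous underneath that binary state.

Axis convention: arrays are indexed ``(z, y, x)`` with ``z`` the longitudinal
(loading) axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage

#: Upper end of the bone-mineral-density calibration range, mg HA/cm^3.
DENSITY_MAX = 1160.0

#: Grayscale value separating bone from marrow (equivalent to 580 mg HA/cm^3).
BONE_THRESHOLD = 0.5

#: Default isotropic voxel edge length, micrometers.
DEFAULT_RESOLUTION_UM = 10.5


class Region(IntEnum):
    """Per-voxel anatomical region label."""

    OUTSIDE = 0
    TRAB_MARROW = 1
    TRAB_BONE = 2
    CORTICAL = 3
    IVD = 4


def grayscale_from_density(density):
    """Convert bone mineral density (mg HA/cm^3) to grayscale in [0, 1].

    The map is exactly linear: ``grayscale = density / 1160``.  Raises
    ``ValueError`` outside the calibration range [0, 1160].
    """
    density = np.asarray(density, dtype=float)
    if np.any(density < 0.0) or np.any(density > DENSITY_MAX):
        raise ValueError(
            f"density outside calibration range [0, {DENSITY_MAX}] mg HA/cm^3"
        )
    out = density / DENSITY_MAX
    return out if out.ndim else float(out)


def density_from_grayscale(grayscale):
    """Inverse calibration: grayscale in [0, 1] back to mg HA/cm^3."""
    grayscale = np.asarray(grayscale, dtype=float)
    if np.any(grayscale < 0.0) or np.any(grayscale > 1.0):
        raise ValueError("grayscale outside [0, 1]")
    out = grayscale * DENSITY_MAX
    return out if out.ndim else float(out)


@dataclass
class TissueGrid:
    """State of the voxel lattice.

    Attributes
    ----------
    grayscale : (nz, ny, nx) float array in [0, 1]
    mineral, osteoid : float arrays in [0, 1]; continuous matrix state.
    region : uint8 array of :class:`Region` labels (a partition of the grid).
    resolution : voxel edge length in micrometers.
    """

    grayscale: np.ndarray
    mineral: np.ndarray = None
    osteoid: np.ndarray = None
    region: np.ndarray = None
    resolution: float = DEFAULT_RESOLUTION_UM

    def __post_init__(self):
        self.grayscale = np.asarray(self.grayscale, dtype=float)
        shape = self.grayscale.shape
        if self.mineral is None:
            self.mineral = np.zeros(shape)
        if self.osteoid is None:
            self.osteoid = np.zeros(shape)
        if self.region is None:
            self.region = np.full(shape, Region.TRAB_MARROW, dtype=np.uint8)
        for name in ("mineral", "osteoid"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")

    @property
    def shape(self):
        return self.grayscale.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.resolution * 1e-3) ** 3

    def bone_mask(self, threshold: float = BONE_THRESHOLD) -> np.ndarray:
        """Binary bone phase inside the trabecular region."""
        return segment_bone(self.grayscale, threshold) & (
            self.region == Region.TRAB_BONE
        )

    def marrow_mask(self) -> np.ndarray:
        return self.region == Region.TRAB_MARROW

    def trabecular_mask(self) -> np.ndarray:
        return (self.region == Region.TRAB_BONE) | (self.region == Region.TRAB_MARROW)

    def validate(self):
        if np.any(self.mineral < 0) or np.any(self.mineral > 1):
            raise ValueError("mineral concentration out of [0, 1]")
        if np.any(self.osteoid < 0) or np.any(self.osteoid > 1):
            raise ValueError("osteoid concentration out of [0, 1]")

    def copy(self) -> "TissueGrid":
        return TissueGrid(
            grayscale=self.grayscale.copy(),
            mineral=self.mineral.copy(),
            osteoid=self.osteoid.copy(),
            region=self.region.copy(),
            resolution=self.resolution,
        )


def segment_bone(grayscale: np.ndarray, threshold: float = BONE_THRESHOLD) -> np.ndarray:
    """Binary bone mask: true iff grayscale >= threshold."""
    return np.asarray(grayscale) >= threshold


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def greatest_connected_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest connected component of a binary mask.

    Connectivity is 6, 18 or 26 (default 26, the usual choice for the bone
    phase of micro-CT images).  Ties between equally sized components are
    broken in favor of the component containing the lexicographically
    smallest (z, y, x) voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no connected components")
    labels, n = ndimage.label(mask, structure=_CONNECTIVITY_STRUCTS[connectivity])
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # tie-break: component whose first voxel in C scan order (z, y, x)
        # comes first
        flat = labels.ravel()
        first = {lab: np.argmax(flat == lab) for lab in candidates}
        keep = min(candidates, key=lambda lab: first[lab])
    return labels == keep


def init_tissue_state(mask: np.ndarray, resolution: float = DEFAULT_RESOLUTION_UM) -> TissueGrid:
    """Initialize a :class:`TissueGrid` from a segmented bone mask.

    Bone voxels get mineral = osteoid = 1 (fully mineralized matrix) and
    grayscale 1; everything else is trabecular marrow with zero matrix.
    """
    mask = np.asarray(mask, dtype=bool)
    grid = TissueGrid(
        grayscale=mask.astype(float),
        mineral=mask.astype(float),
        osteoid=mask.astype(float),
        region=np.where(mask, Region.TRAB_BONE, Region.TRAB_MARROW).astype(np.uint8),
        resolution=resolution,
    )
    return grid


def update_bone_phase(grid: TissueGrid) -> np.ndarray:
    """Re-segment the bone phase from the mineral concentration.

    A trabecular voxel joins the bone phase when its mineral concentration
    reaches the segmentation threshold and leaves it when the mineral drops
    below.  Grayscale tracks the mineral concentration inside the trabecular
    region; region labels are updated in place.  Returns the new bone mask.
    """
    trab = grid.trabecular_mask()
    grid.grayscale[trab] = grid.mineral[trab]
    bone = trab & (grid.mineral >= BONE_THRESHOLD)
    grid.region[trab] = np.where(bone[trab], Region.TRAB_BONE, Region.TRAB_MARROW)
    return bone


# ---------------------------------------------------------------------------
# 3D volume I/O (MetaImage, NIfTI, VTK) via SimpleITK
# ---------------------------------------------------------------------------

def write_volume(path, array: np.ndarray, resolution: float = DEFAULT_RESOLUTION_UM):
    """Write a scalar volume (.mha/.mhd, .nii/.nii.gz or .vtk).

    The array is interpreted as (z, y, x); voxel spacing is isotropic in
    micrometers.  Label volumes should be passed as uint8.
    """
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(array))
    img.SetSpacing((resolution, resolution, resolution))
    sitk.WriteImage(sitk.Cast(img, img.GetPixelID()), str(path))


def read_volume(path):
    """Read a scalar volume; returns (array (z, y, x), resolution um)."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img), float(img.GetSpacing()[0])
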