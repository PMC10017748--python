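"""Synthetic vertebral phantoms and initial cell populations.

The in vivo micro-CT images this model was designed around are not part of
the package, so every downstream stage is exercised on synthetic
microarchitectures: a trabecular core (Gaussian random field, rod lattice or
plate slab) with a tunable bone volume fraction, wrapped in a cylindrical
cortical shell, with soft cylindrical pads at both longitudinal ends playing
the role of the intervertebral discs in the FE boundary conditions.

Cell seeding mirrors the model-generation recipe: MSCs and HSCs are placed
randomly in trabecular marrow at 1.25e7 cells/mL each; osteocytes are
embedded in bone with an exponential depth bias (deeper voxels more likely);
osteoblasts, osteoclasts and preosteoclasts occupy random disjoint fractions
of the bone surface with partially bound receptors.

All generators are exactly reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .agents import Cell
from .grid import DEFAULT_RESOLUTION_UM, Region, TissueGrid
from .signaling import ReceptorPool


@dataclass
class PhantomSpec:
    """Geometry of a synthetic vertebra phantom."""

    shape: tuple = (48, 48, 48)  # (nz, ny, nx) voxels
    resolution: float = DEFAULT_RESOLUTION_UM  # um
    target_bvtv: float = 0.2
    style: str = "gaussian_field"  # gaussian_field | rod_lattice | plate_slab
    cortical_shell_thickness: int = 2  # voxels
    ivd_pad_height: int = 3  # voxels
    rng_seed: int = 0
    smoothing_sigma: float = 2.5  # voxels, gaussian_field style
    rod_pitch: int = 10  # voxels, rod_lattice style
    slab_thickness: int = None  # voxels, plate_slab style
    bvtv_tol: float = 0.02

    def __post_init__(self):
        if not (0.0 < self.target_bvtv < 1.0):
            raise ValueError("target_bvtv must be in (0, 1)")


@dataclass
class SeedingSpec:
    """Cell seeding densities and fractions."""

    msc_density: float = 1.25e7  # cells/mL
    hsc_density: float = 1.25e7  # cells/mL
    ot_per_bone_voxel: float = 0.1  # expected osteocytes per bone voxel
    ot_depth_scale: float = 30.0  # um, exponential depth-bias scale
    ob_surface_fraction: float = 0.15
    oc_surface_fraction: float = 0.08
    preoc_surface_fraction: float = 0.08
    bound_fraction_range: tuple = (0.2, 0.8)
    rank_sites: float = 1.0
    lrp_sites: float = 1.0
    tgfbr_sites: float = 1.0
    kf: float = 1.0  # per concentration per min
    kr: float = 0.01  # 1/min
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.msc_density, self.hsc_density) < 0:
            raise ValueError("densities must be >= 0")
        fr = (
            self.ob_surface_fraction
            + self.oc_surface_fraction
            + self.preoc_surface_fraction
        )
        if fr > 1.0:
            raise ValueError("surface fractions sum above 1")


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def _cylinder_mask(shape):
    _, ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    Y, X = np.meshgrid(y, x, indexing="ij")
    R = min(ny, nx) / 2.0 - 0.5
    return (Y**2 + X**2) <= R**2, np.sqrt(Y**2 + X**2), R


def _core_bone_field(spec: PhantomSpec, core_shape, rng):
    """Continuous field whose upper quantile defines the bone phase."""
    if spec.style == "gaussian_field":
        noise = rng.standard_normal(core_shape)
        return ndimage.gaussian_filter(noise, spec.smoothing_sigma, mode="wrap")
    if spec.style == "rod_lattice":
        p = spec.rod_pitch
        z = (np.arange(core_shape[0]) + 0.5) % p - p / 2.0
        y = (np.arange(core_shape[1]) + 0.5) % p - p / 2.0
        x = (np.arange(core_shape[2]) + 0.5) % p - p / 2.0
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        d_rod_x = np.sqrt(Z**2 + Y**2)
        d_rod_y = np.sqrt(Z**2 + X**2)
        d_rod_z = np.sqrt(Y**2 + X**2)
        return -np.minimum(np.minimum(d_rod_x, d_rod_y), d_rod_z)
    raise ValueError(f"unknown phantom style {spec.style!r}")


def make_trabecular_phantom(spec: PhantomSpec) -> TissueGrid:
    """Build a synthetic phantom as a :class:`TissueGrid`.

    Regions: cylindrical IVD pads at both z ends, a cortical shell on the
    lateral cylinder surface between the pads, a trabecular core (bone +
    marrow) inside, and OUTSIDE elsewhere.  Bone voxels get grayscale =
    mineral = osteoid = 1.  The core bone fraction is matched to
    ``target_bvtv`` by thresholding the generator field at the matching
    quantile (verified to ``bvtv_tol``).
    """
    nz, ny, nx = spec.shape
    pad = spec.ivd_pad_height
    shell = spec.cortical_shell_thickness
    if nz <= 2 * pad + 2:
        raise ValueError("shape too small for the IVD pads")
    rng = np.random.default_rng(spec.rng_seed)

    inside, rdist, R = _cylinder_mask(spec.shape)
    region = np.full(spec.shape, Region.OUTSIDE, dtype=np.uint8)
    region[:pad][:, inside] = Region.IVD
    region[nz - pad:][:, inside] = Region.IVD

    mid = np.zeros(spec.shape, dtype=bool)
    mid[pad : nz - pad] = True
    shell_mask = mid & inside[None, :, :] & (rdist > R - shell)[None, :, :]
    core_mask = mid & inside[None, :, :] & ~shell_mask
    region[shell_mask] = Region.CORTICAL

    core_shape = (nz - 2 * pad, ny, nx)
    if spec.style == "plate_slab":
        t = spec.slab_thickness
        if t is None:
            t = max(1, int(round(spec.target_bvtv * core_shape[0])))
        z0 = (core_shape[0] - t) // 2
        bone_core = np.zeros(core_shape, dtype=bool)
        bone_core[z0 : z0 + t] = True
    else:
        # rank-select the top target fraction of the generator field inside
        # the core: exact BV/TV, deterministic tie-break by scan order
        fld = _core_bone_field(spec, core_shape, rng)
        core_flat = core_mask[pad : nz - pad]
        idx = np.flatnonzero(core_flat.ravel())
        vals = fld.ravel()[idx]
        n_target = int(round(spec.target_bvtv * len(idx)))
        order = np.argsort(-vals, kind="stable")[:n_target]
        bone_core = np.zeros(core_shape, dtype=bool)
        bone_core.ravel()[idx[order]] = True

    bone = np.zeros(spec.shape, dtype=bool)
    bone[pad : nz - pad] = bone_core
    bone &= core_mask

    region[core_mask] = Region.TRAB_MARROW
    region[bone] = Region.TRAB_BONE

    if spec.style != "plate_slab":
        bvtv = bone.sum() / core_mask.sum()
        if abs(bvtv - spec.target_bvtv) > spec.bvtv_tol:
            raise ValueError(
                f"could not reach target BV/TV {spec.target_bvtv} "
                f"(got {bvtv:.3f})"
            )

    solid = bone | shell_mask
    grayscale = solid.astype(float)
    grid = TissueGrid(
        grayscale=grayscale,
        mineral=bone.astype(float),
        osteoid=bone.astype(float),
        region=region,
        resolution=spec.resolution,
    )
    return grid


def measured_bvtv(grid: TissueGrid) -> float:
    """Bone volume fraction of the trabecular core."""
    trab = grid.trabecular_mask()
    return float((grid.region == Region.TRAB_BONE).sum() / trab.sum())


# ---------------------------------------------------------------------------
# cell seeding
# ---------------------------------------------------------------------------

def _pool_factories(spec: SeedingSpec):
    return {
        "RANK": lambda: ReceptorPool("RANK", spec.rank_sites, 0.0, spec.kf, spec.kr),
        "LRP56": lambda: ReceptorPool("LRP56", spec.lrp_sites, 0.0, spec.kf, spec.kr),
        "TGFBR": lambda: ReceptorPool("TGFBR", spec.tgfbr_sites, 0.0, spec.kf, spec.kr),
    }


def _receptors(kind, spec, rng=None):
    from .agents import _receptors_for

    recs = _receptors_for(kind, _pool_factories(spec))
    if rng is not None:
        lo, hi = spec.bound_fraction_range
        for pool in recs.values():
            pool.bound = pool.total_sites * rng.uniform(lo, hi)
    return recs


def seed_marrow_cells(grid: TissueGrid, spec: SeedingSpec,
                      start_id: int = 0) -> list:
    """Seed MSCs and HSCs in random distinct trabecular-marrow voxels.

    Per-type counts are binomial with success probability
    ``density * voxel_volume_mL`` per marrow voxel, matching the target
    volumetric density in expectation.
    """
    marrow = np.argwhere(grid.region == Region.TRAB_MARROW)
    if len(marrow) == 0:
        raise ValueError("no marrow voxels to seed")
    rng = np.random.default_rng(spec.rng_seed)
    vol_mL = (grid.resolution * 1e-4) ** 3  # um -> cm, voxel volume in cm^3
    cells = []
    order = rng.permutation(len(marrow))
    used = 0
    nid = start_id
    for kind, density in (("MSC", spec.msc_density), ("HSC", spec.hsc_density)):
        p = density * vol_mL
        if p > 1.0:
            raise ValueError("cell density exceeds one cell per voxel")
        n = rng.binomial(len(marrow), p)
        if used + n > len(marrow):
            raise ValueError("cell density too high for available marrow voxels")
        for i in order[used : used + n]:
            cells.append(
                Cell(id=nid, kind=kind, position=tuple(marrow[i]),
                     receptors=_receptors(kind, spec, rng))
            )
            nid += 1
        used += n
    return cells


def bone_depth(grid: TissueGrid) -> np.ndarray:
    """Distance (um) from each bone voxel to the nearest non-bone voxel."""
    bone = grid.region == Region.TRAB_BONE
    return ndimage.distance_transform_edt(bone) * grid.resolution


def seed_osteocytes(grid: TissueGrid, spec: SeedingSpec,
                    start_id: int = 0, n_cells: int = None) -> list:
    """Embed osteocytes in bone with an exponential depth bias.

    Sampling weight of a bone voxel at depth d (um) is proportional to
    ``exp(d / ot_depth_scale)`` -- deeper voxels are more likely, and the
    distribution tends to uniform as the scale goes to infinity.  The count
    defaults to ``ot_per_bone_voxel`` times the number of bone voxels.
    Voxels are sampled without replacement.
    """
    bone_idx = np.argwhere(grid.region == Region.TRAB_BONE)
    if len(bone_idx) == 0:
        raise ValueError("no bone voxels to seed")
    rng = np.random.default_rng(spec.rng_seed + 1)
    if n_cells is None:
        n_cells = int(round(spec.ot_per_bone_voxel * len(bone_idx)))
    if n_cells == 0:
        return []
    if n_cells > len(bone_idx):
        raise ValueError("more osteocytes requested than bone voxels")
    depth = bone_depth(grid)[tuple(bone_idx.T)]
    logw = depth / spec.ot_depth_scale
    w = np.exp(logw - logw.max())
    w /= w.sum()
    chosen = rng.choice(len(bone_idx), size=n_cells, replace=False, p=w)
    return [
        Cell(id=start_id + i, kind="Ot", position=tuple(bone_idx[j]))
        for i, j in enumerate(chosen)
    ]


def bone_surface_mask(grid: TissueGrid) -> np.ndarray:
    """Bone voxels 6-adjacent to trabecular marrow."""
    bone = grid.region == Region.TRAB_BONE
    marrow = grid.region == Region.TRAB_MARROW
    struct = ndimage.generate_binary_structure(3, 1)
    return bone & ndimage.binary_dilation(marrow, structure=struct)


def seed_surface_cells(grid: TissueGrid, spec: SeedingSpec,
                       start_id: int = 0) -> list:
    """Seed Ob, Oc and preOc on disjoint random bone-surface voxels.

    Counts are binomial at the configured fractions of the surface voxel
    count; receptors start partially bound, uniformly in
    ``bound_fraction_range``.
    """
    surf = np.argwhere(bone_surface_mask(grid))
    if len(surf) == 0:
        raise ValueError("no bone surface voxels")
    rng = np.random.default_rng(spec.rng_seed + 2)
    order = rng.permutation(len(surf))
    cells = []
    used = 0
    nid = start_id
    for kind, frac in (
        ("Ob", spec.ob_surface_fraction),
        ("Oc", spec.oc_surface_fraction),
        ("preOc", spec.preoc_surface_fraction),
    ):
        n = rng.binomial(len(surf), frac) if frac > 0 else 0
        n = min(n, len(surf) - used)
        for i in order[used : used + n]:
            cells.append(
                Cell(id=nid, kind=kind, position=tuple(surf[i]),
                     receptors=_receptors(kind, spec, rng))
            )
            nid += 1
        used += n
    return cells


def seed_all(grid: TissueGrid, spec: SeedingSpec) -> list:
    """Full seeding: marrow stem cells, osteocytes, surface cells."""
    cells = seed_marrow_cells(grid, spec)
    cells += seed_osteocytes(grid, spec, start_id=len(cells))
    cells += seed_surface_cells(grid, spec, start_id=len(cells))
    return cells


def cells_to_table(cells) -> "object":
    """Cell list as a pandas DataFrame (id, kind, z, y, x, occupancies)."""
    import pandas as pd

    rows = []
    for c in cells:
        row = {"id": c.id, "kind": c.kind,
               "z": c.position[0], "y": c.position[1], "x": c.position[2]}
        for name, pool in c.receptors.items():
            row[f"occ_{name}"] = pool.occupancy
        rows.append(row)
    return pd.DataFrame(rows)
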