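"""Synthetic phantoms standing in for the study's real inputs: the
homogeneous lung cube, a clinical-like thorax with tumor/PTV/lung
structures, and HU→density conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage

from .grids import VoxelPhantom

THORAX_MATERIALS = ("air", "lung_icrp", "water", "muscle_icrp")


@dataclass
class PhantomSpec:
    """Parameters of a generated phantom.

    ``lung_cube`` defaults: 1 cm³ at 0.05 mm isotropic spacing, uniform
    0.26 g/cm³ ICRP lung. ``thorax`` defaults: CT-like 0.69×0.69×1.0 mm
    grid, lung densities clipped to [0.01, 0.6] g/cm³, a 3.9 cm³ tumor,
    a 12.8 cm³ PTV and ~895 cm³ of lung.
    """

    scenario: str = "lung_cube"
    spacing_mm: tuple[float, float, float] = (0.05, 0.05, 0.05)
    side_mm: float = 10.0
    lung_density: float = 0.26
    # thorax parameters
    tumor_center_cm: tuple[float, float, float] = (3.93, 2.94, -0.141)
    tumor_volume_cm3: float = 3.9
    tumor_diameter_cm: float | None = None  # fallback mode: fixed diameter
    ptv_volume_cm3: float = 12.8
    lung_density_range: tuple[float, float] = (0.01, 0.6)
    noise_sigma: float = 0.12
    correlation_mm: float = 5.0
    seed: int = 0


def make_lung_cube(spec: PhantomSpec | None = None) -> VoxelPhantom:
    """Homogeneous lung cube; the world the ideal electron studies use.

    Default 200³ voxels of 0.05 mm (1 cm³). Electrons leaving the cube
    escape the world, as in the original setup.
    """
    spec = spec or PhantomSpec()
    sp = np.asarray(spec.spacing_mm, float)
    dims = tuple(int(round(spec.side_mm / s)) for s in sp)
    origin = -sp * np.asarray(dims) / 2.0
    matidx = np.zeros(dims, dtype=np.uint8)
    density = np.full(dims, spec.lung_density)
    return VoxelPhantom(origin, sp, matidx, density, ("lung_icrp",))


def _grow_mask(dist: np.ndarray, inside: np.ndarray,
               n_target: int) -> np.ndarray:
    """Select the n_target voxels of smallest ``dist`` within ``inside``
    (deterministic tie-break by flat index)."""
    flat = np.flatnonzero(inside)
    if len(flat) < n_target:
        raise ValueError("region too small to reach the target volume")
    order = np.lexsort((flat, dist.ravel()[flat]))
    chosen = flat[order[:n_target]]
    mask = np.zeros(dist.shape, dtype=bool)
    mask.ravel()[chosen] = True
    return mask


def make_thorax_phantom(spec: PhantomSpec | None = None):
    """Clinical-like thorax phantom with structure masks.

    Returns ``(phantom, masks)`` where ``masks`` has boolean arrays
    ``tumor``, ``ptv`` and ``lung``. Two elliptic-cylinder lungs filled
    with a correlated Gaussian density field (clipped to the stated
    range) sit in a muscle-density body; the tumor is a water-density
    sphere grown voxel-wise to the stated volume, the PTV an isotropic
    margin grown the same way.
    """
    spec = spec or PhantomSpec(scenario="thorax")
    rng = np.random.default_rng(spec.seed)
    sp = np.array([0.69, 0.69, 1.0])
    dims = (340, 240, 60)
    origin = np.array([-dims[0] * sp[0] / 2, -dims[1] * sp[1] / 2,
                       -dims[2] * sp[2] / 2])
    x = origin[0] + (np.arange(dims[0]) + 0.5) * sp[0]
    y = origin[1] + (np.arange(dims[1]) + 0.5) * sp[1]
    z = origin[2] + (np.arange(dims[2]) + 0.5) * sp[2]
    X, Y = np.meshgrid(x, y, indexing="ij")

    vox_cm3 = float(np.prod(sp)) / 1000.0
    height_cm = dims[2] * sp[2] / 10.0

    # two lungs sized so the pair holds ~895 cm³ over the slab height
    lung_area_cm2 = 895.2 / height_cm / 2.0  # per lung
    a_cm = 4.6  # semi-axis x
    b_cm = lung_area_cm2 / (math.pi * a_cm)
    centers = [(-55.0, 15.0), (55.0, 15.0)]  # mm
    lung2d = np.zeros(dims[:2], dtype=bool)
    for cx, cy in centers:
        lung2d |= ((X - cx) / (a_cm * 10)) ** 2 + \
                  ((Y - cy) / (b_cm * 10)) ** 2 <= 1.0
    body2d = (X / 115.0) ** 2 + (Y / 85.0) ** 2 <= 1.0
    lung3d = np.repeat(lung2d[:, :, None], dims[2], axis=2)
    body3d = np.repeat(body2d[:, :, None], dims[2], axis=2)

    # correlated lung density noise, clipped to the stated range
    white = rng.standard_normal(dims)
    sigma_vox = spec.correlation_mm / sp
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    smooth /= smooth.std()
    lo, hi = spec.lung_density_range
    lung_rho = np.clip(0.26 + spec.noise_sigma * smooth, lo, hi)

    density = np.where(body3d, 1.05, 1.2048e-3)
    matidx = np.where(body3d, 3, 0).astype(np.uint8)  # muscle / air
    density[lung3d] = lung_rho[lung3d]
    matidx[lung3d] = 1  # lung

    # tumor: the stated 2.8 cm diameter and 3.9 cm³ volume are mutually
    # inconsistent for a sphere; both hold for a prolate ellipsoid whose
    # long axis (2.8 cm) follows the catheter direction, which is how a
    # contoured lesion threaded by a single catheter looks. The mask is
    # grown voxel-wise in the ellipsoidal metric to the exact volume.
    ctr = np.asarray(spec.tumor_center_cm) * 10.0
    a_ax = math.radians(-152.0)
    axis = np.array([math.sin(a_ax), math.cos(a_ax), 0.0])
    dx = x[:, None, None] - ctr[0]
    dy = y[None, :, None] - ctr[1]
    dz = z[None, None, :] - ctr[2]
    if spec.tumor_diameter_cm is not None:
        # fallback: plain sphere of the stated diameter
        r = spec.tumor_diameter_cm * 10.0 / 2.0
        tumor = dx * dx + dy * dy + dz * dz <= r * r
    else:
        a_mm = 14.0  # semi-axis along the catheter (2.8 cm diameter)
        b_mm = math.sqrt(spec.tumor_volume_cm3 * 1000.0 * 3.0 /
                         (4.0 * math.pi * a_mm))
        u = dx * axis[0] + dy * axis[1] + dz * axis[2]
        perp2 = dx * dx + dy * dy + dz * dz - u * u
        met = (u / a_mm) ** 2 + perp2 / (b_mm * b_mm)
        n_t = int(round(spec.tumor_volume_cm3 / vox_cm3))
        tumor = _grow_mask(met, np.ones(dims, dtype=bool), n_t)
    # PTV: isotropic margin grown from the tumor surface to the volume
    dist_out = ndimage.distance_transform_edt(~tumor, sampling=sp)
    n_p = int(round(spec.ptv_volume_cm3 / vox_cm3))
    ptv = _grow_mask(dist_out, np.ones(dims, dtype=bool), n_p)
    ptv |= tumor  # guaranteed superset

    density[tumor] = 1.0
    matidx[tumor] = 2  # water
    lung_mask = (matidx == 1) & ~tumor

    phantom = VoxelPhantom(origin, sp, matidx, density, THORAX_MATERIALS)
    masks = {"tumor": tumor, "ptv": ptv, "lung": lung_mask}
    return phantom, masks


# HU→density anchor points (piecewise linear, Schneider-style segments:
# air → lung → adipose/soft tissue → bone). HU = 0 maps to water by the
# definition of the Hounsfield scale.
_HU_POINTS = np.array([-1000.0, -98.0, 0.0, 100.0, 1000.0, 2000.0])
_RHO_POINTS = np.array([0.00121, 0.930, 1.000, 1.0695, 1.617, 2.201])


def hu_to_density(hu_grid) -> np.ndarray:
    """Piecewise-linear CT-number → mass-density conversion [g/cm³]."""
    hu = np.asarray(hu_grid, dtype=float)
    if np.any(hu < -1000.0) or np.any(hu > 2000.0):
        warnings.warn("HU values outside [-1000, 2000] clamped",
                      stacklevel=2)
        hu = np.clip(hu, -1000.0, 2000.0)
    return np.interp(hu, _HU_POINTS, _RHO_POINTS)


def density_to_material_index(density: np.ndarray) -> np.ndarray:
    """Map density to the thorax material set (air/lung/water/muscle)
    for cross-section lookup, keeping the continuous density for mass."""
    idx = np.full(density.shape, 2, dtype=np.uint8)  # water default
    idx[density < 0.05] = 0
    idx[(density >= 0.05) & (density < 0.7)] = 1
    idx[density >= 1.02] = 3
    return idx
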