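"""Voxel phantoms and dose grids, plus volumetric file I/O.

Coordinate convention: grid indices are 0-based; voxel ``(i, j, k)``
spans the half-open box ``[origin + i*spacing, origin + (i+1)*spacing)``
in mm, per axis. Positions are in mm in the phantom frame.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class VoxelPhantom:
    """3D grid of material indices and mass densities.

    ``materials`` maps index -> material name (resolved against the
    material registry by the transport layer).
    """

    origin: np.ndarray  # mm, (3,)
    spacing: np.ndarray  # mm, (3,)
    material_index: np.ndarray  # (nx, ny, nz) uint8
    density: np.ndarray  # (nx, ny, nz) g/cm³
    materials: tuple[str, ...]

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.material_index.shape != self.density.shape:
            raise ValueError("material_index and density shapes differ")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.material_index.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_of(self, point_mm) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(point_mm) - self.origin) / self.spacing)
        return tuple(int(i) for i in idx)

    def contains(self, point_mm) -> bool:
        i, j, k = self.voxel_of(point_mm)
        nx, ny, nz = self.dims
        return 0 <= i < nx and 0 <= j < ny and 0 <= k < nz

    def center_mm(self) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(self.dims) / 2.0


@dataclass
class DoseGrid:
    """Per-voxel dose statistics accumulated over history batches.

    ``mean`` is the batch-mean dose per emitted history (MeV/g unless
    ``unit`` says otherwise); ``sem`` the standard error over batches.
    """

    origin: np.ndarray
    spacing: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_batches: int
    n_histories: int
    unit: str = "MeV/g per history"
    meta: dict = field(default_factory=dict)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mean.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def same_geometry(self, other: "DoseGrid") -> bool:
        return (
            self.mean.shape == other.mean.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def voxel_of(self, point_mm) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(point_mm) - self.origin) / self.spacing)
        return tuple(int(i) for i in idx)

    def scaled(self, factor: float, unit: str | None = None) -> "DoseGrid":
        return DoseGrid(
            self.origin.copy(),
            self.spacing.copy(),
            self.mean * factor,
            self.sem * factor,
            self.n_batches,
            self.n_histories,
            unit or self.unit,
            dict(self.meta),
        )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_dose(dose: DoseGrid, stem: str | Path) -> None:
    """Write a DoseGrid as NIfTI (mean) + sidecar CSV (SEM) + JSON manifest."""
    import nibabel as nib

    stem = Path(stem)
    affine = np.diag(list(dose.spacing) + [1.0])
    affine[:3, 3] = dose.origin
    nib.save(
        nib.Nifti1Image(dose.mean.astype(np.float32), affine),
        str(stem.with_suffix(".nii")),
    )
    flat = dose.sem.astype(np.float32).ravel()
    np.savetxt(
        stem.parent / (stem.name + "_sem.csv"),
        flat[None] if flat.ndim == 1 else flat,
        delimiter=",",
        header="per-voxel SEM, C-order flattened; shape=%s" % (dose.dims,),
    )
    manifest = {
        "unit": dose.unit,
        "n_batches": dose.n_batches,
        "n_histories": dose.n_histories,
        "origin_mm": list(dose.origin),
        "spacing_mm": list(dose.spacing),
        "dims": list(dose.dims),
        **dose.meta,
    }
    (stem.parent / (stem.name + "_manifest.json")).write_text(
        json.dumps(manifest, indent=2, default=str)
    )


def read_dose(stem: str | Path) -> DoseGrid:
    import nibabel as nib

    stem = Path(stem)
    img = nib.load(str(stem.with_suffix(".nii")))
    mean = np.asarray(img.dataobj, dtype=np.float64)
    manifest = json.loads((stem.parent / (stem.name + "_manifest.json")).read_text())
    sem_flat = np.loadtxt(stem.parent / (stem.name + "_sem.csv"), delimiter=",")
    sem = np.asarray(sem_flat, dtype=np.float64).reshape(mean.shape)
    return DoseGrid(
        np.array(manifest["origin_mm"]),
        np.array(manifest["spacing_mm"]),
        mean,
        sem,
        manifest["n_batches"],
        manifest["n_histories"],
        manifest["unit"],
        {k: v for k, v in manifest.items()
         if k not in {"unit", "n_batches", "n_histories", "origin_mm",
                      "spacing_mm", "dims"}},
    )
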