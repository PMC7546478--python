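"""Condensed-history electron and analog photon transport API.

The heavy lifting lives in :mod:`magbrachy._kernels`; this module owns
the user-facing dataclasses, batch orchestration and dose statistics.

Model summary
-------------
Electrons lose energy continuously (Berger–Seltzer stopping power,
CSDA — no δ-rays or straggling by default), are deflected once per
condensed step by a Highland Gaussian, and move between deflections
along the *exact* analytic helix of the uniform field (sub-stepped so
the chord sagitta never exceeds ``chord_tolerance``). Photons undergo
Woodcock (majorant) tracking with free-electron Klein–Nishina Compton
scattering and parametrized photoelectric absorption; their secondary
electrons feel the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .constants import ELECTRON_MASS_MEV
from .grids import DoseGrid, VoxelPhantom
from .tables import PhysicsTables


@dataclass
class ParticleState:
    kind: str  # "photon" | "electron"
    position: np.ndarray  # mm
    direction: np.ndarray  # unit vector
    kinetic_energy: float  # MeV
    weight: float = 1.0
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction norm {n} != 1")
        if self.kinetic_energy < 0:
            raise ValueError("kinetic energy must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass(frozen=True)
class FieldSpec:
    """Uniform magnetic field over the world [T]."""

    B: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not all(math.isfinite(b) for b in self.B):
            raise ValueError("field components must be finite")

    @property
    def magnitude(self) -> float:
        return math.sqrt(sum(b * b for b in self.B))


@dataclass(frozen=True)
class TransportParams:
    chord_tolerance: float = 0.05  # mm, max helix-chord sagitta
    dr_over_range: float = 0.2  # fraction of CSDA range per step
    final_range: float = 10.0  # μm, residual range deposited locally
    electron_cutoff: float = 10.0  # keV
    photon_cutoff: float = 5.0  # keV
    max_step: float = 2.0  # mm
    scattering: bool = True
    delta_rays: bool = False  # discrete Møller δ production
    delta_range_cut: float = 0.05  # mm, production range cut
    straggling: bool = False  # Bohr straggling on the continuous loss

    def __post_init__(self):
        for name in ("chord_tolerance", "dr_over_range", "final_range",
                     "electron_cutoff", "photon_cutoff", "max_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def gyroradius(kinetic_energy: float, b_tesla: float) -> float:
    """Gyroradius [mm] of an electron moving perpendicular to B."""
    pc = math.sqrt(kinetic_energy * (kinetic_energy + 2 * ELECTRON_MASS_MEV))
    return pc / (K.GYRO * b_tesla)


def helical_step(state: ParticleState, fieldspec: FieldSpec,
                 step_length: float,
                 chord_tolerance: float = 0.05) -> ParticleState:
    """Advance an electron by ``step_length`` mm along the exact helix.

    Kinetic energy is unchanged (energy loss is applied separately by
    the condensed-history loop). With B = 0 this is a straight step.
    """
    if state.kind != "electron":
        raise ValueError("helical_step applies to electrons")
    if step_length <= 0:
        raise ValueError("step_length must be positive")
    bx, by, bz = fieldspec.B
    bmag = fieldspec.magnitude
    p = state.position.astype(float)
    d = state.direction.astype(float)
    if bmag == 0.0:
        return replace(state, position=p + d * step_length,
                       direction=d.copy())
    pc = math.sqrt(state.kinetic_energy *
                   (state.kinetic_energy + 2 * ELECTRON_MASS_MEV))
    kmag = K.GYRO * bmag / pc
    kv = kmag * np.array([bx, by, bz]) / bmag
    # sub-step so each chord's sagitta stays below tolerance
    smax = math.sqrt(8.0 * chord_tolerance / kmag)
    nsub = max(1, int(math.ceil(step_length / smax)))
    ssub = step_length / nsub
    px, py, pz = p
    dx, dy, dz = d
    for _ in range(nsub):
        px, py, pz, dx, dy, dz = K._helix_advance(
            px, py, pz, dx, dy, dz, ssub, kv[0], kv[1], kv[2], kmag)
    return replace(state, position=np.array([px, py, pz]),
                   direction=np.array([dx, dy, dz]))


def _split_batches(n_histories: int, n_batches: int) -> list[int]:
    base = n_histories // n_batches
    sizes = [base] * n_batches
    for i in range(n_histories - base * n_batches):
        sizes[i] += 1
    return sizes


class ConservationError(RuntimeError):
    pass


def run_histories(source_spec, phantom: VoxelPhantom, fieldspec: FieldSpec,
                  params: TransportParams, n_histories: int,
                  n_batches: int = 10, seed: int = 0,
                  tables: PhysicsTables | None = None) -> DoseGrid:
    """Run a full simulation and return the batch-averaged DoseGrid.

    Histories are split evenly over batches, each with an independent
    RNG substream derived from ``seed``; the per-voxel SEM is the
    standard error of the batch means. Identical (seed, configuration)
    reruns are bit-identical.
    """
    if n_histories <= 0:
        raise ValueError("n_histories must be positive")
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    tables = tables or PhysicsTables(phantom.materials)
    if tuple(tables.material_names) != tuple(phantom.materials):
        raise ValueError("tables material order does not match phantom")

    matidx = np.ascontiguousarray(phantom.material_index, dtype=np.uint8)
    density = np.ascontiguousarray(phantom.density, dtype=np.float64)
    ox, oy, oz = phantom.origin
    sx, sy, sz = phantom.spacing
    bx, by, bz = fieldspec.B

    mass = density * phantom.voxel_volume_cm3  # g per voxel
    dose_sum = np.zeros(phantom.dims)
    dose_sq = np.zeros(phantom.dims)

    sizes = _split_batches(n_histories, n_batches)
    tally = {"emitted": 0.0, "deposited": 0.0, "escaped": 0.0,
             "absorbed_in_seed": 0.0, "max_residual": 0.0}
    for b, nb in enumerate(sizes):
        edep = np.zeros(phantom.dims)
        res = source_spec._run_batch(
            nb, matidx, density, ox, oy, oz, sx, sy, sz,
            bx, by, bz, tables, params, edep, seed, b)
        tally["emitted"] += res[0]
        tally["deposited"] += res[1]
        tally["escaped"] += res[2]
        if len(res) > 4:
            tally["absorbed_in_seed"] += res[3]
            tally["max_residual"] = max(tally["max_residual"], res[4])
        else:
            tally["max_residual"] = max(tally["max_residual"], res[3])
        with np.errstate(divide="ignore", invalid="ignore"):
            dose_b = np.where(mass > 0, edep / np.where(mass > 0, mass, 1.0), 0.0)
        dose_b /= nb
        dose_sum += dose_b
        dose_sq += dose_b * dose_b

    nB = n_batches
    mean = dose_sum / nB
    var = np.maximum(dose_sq / nB - mean * mean, 0.0) * nB / (nB - 1)
    sem = np.sqrt(var / nB)
    mean_e = tally["emitted"] / n_histories if n_histories else 0.0
    if tally["max_residual"] > 1e-9 * max(mean_e, 1e-12):
        raise ConservationError(
            f"per-history energy conservation violated: max residual "
            f"{tally['max_residual']:.3e} MeV")
    meta = {
        "seed": seed,
        "field_T": list(fieldspec.B),
        "source": getattr(source_spec, "describe", lambda: "unknown")(),
        "conservation": tally,
    }
    return DoseGrid(phantom.origin.copy(), phantom.spacing.copy(),
                    mean, sem, nB, n_histories, meta=meta)
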