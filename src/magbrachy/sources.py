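"""Particle sources: point electron emitters (mono/spectrum), the Ir-192
gamma-line spectrum, the VS2000-style encapsulated seed and weighted
multi-dwell treatment plans.

Seed pose convention: the seed axis lies in the xy-plane making the
stated angle with the +y axis (negative = clockwise when viewed from
+z). Worked example: for the default plan angle of −152°,
axis = (sin(−152°), cos(−152°), 0) ≈ (−0.4695, −0.8829, 0).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from . import materials as mat
from .grids import DoseGrid, VoxelPhantom
from .tables import PhysicsTables


@dataclass(frozen=True)
class SpectrumHistogram:
    """Probability histogram of kinetic energies [MeV]."""

    bin_edges: np.ndarray  # ascending, n+1
    probabilities: np.ndarray  # n, sums to 1

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        prob = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", prob)
        if edges.ndim != 1 or len(edges) != len(prob) + 1:
            raise ValueError("need n+1 edges for n probabilities")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        if np.any(prob < 0):
            raise ValueError("probabilities must be non-negative")
        if len(prob) == 0 or prob.sum() == 0:
            raise ValueError("empty spectrum")
        if abs(prob.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {prob.sum()}, not 1")

    @property
    def max_energy(self) -> float:
        nz = np.nonzero(self.probabilities)[0]
        return float(self.bin_edges[nz[-1] + 1])

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.bin_edges[1:], self.probabilities])
        np.savetxt(path, arr, delimiter=",",
                   header="bin_upper_edge_MeV,probability", comments="")

    @classmethod
    def from_csv(cls, path) -> "SpectrumHistogram":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        uppers = arr[:, 0]
        prob = arr[:, 1]
        edges = np.concatenate(([0.0], uppers))
        return cls(edges, prob / prob.sum())


_IR192_CACHE: list[tuple[float, float]] | None = None


def ir192_lines() -> list[tuple[float, float]]:
    """Principal Ir-192 gamma lines as (energy MeV, intensity per decay).

    Embedded package data (ascending energies, intensities > 0); all
    lines are below the 1.022 MeV pair-production threshold.
    """
    global _IR192_CACHE
    if _IR192_CACHE is None:
        path = importlib.resources.files("magbrachy.data") / "ir192_lines.csv"
        arr = np.loadtxt(str(path), delimiter=",", comments="#", ndmin=2)
        _IR192_CACHE = [(float(e), float(i)) for e, i in arr]
    return list(_IR192_CACHE)


def emit_point_electron(position, energy_or_spectrum,
                        rng: np.random.Generator):
    """Emit one isotropic electron from a point source.

    ``energy_or_spectrum`` is either a kinetic energy [MeV] or a
    :class:`SpectrumHistogram` (sampled uniformly within the chosen bin).
    """
    from .transport import ParticleState

    cz = 2.0 * rng.random() - 1.0
    phi = 2.0 * math.pi * rng.random()
    sz = math.sqrt(max(0.0, 1.0 - cz * cz))
    direction = np.array([sz * math.cos(phi), sz * math.sin(phi), cz])
    if isinstance(energy_or_spectrum, SpectrumHistogram):
        spec = energy_or_spectrum
        idx = rng.choice(len(spec.probabilities), p=spec.probabilities)
        e = rng.uniform(spec.bin_edges[idx], spec.bin_edges[idx + 1])
    else:
        e = float(energy_or_spectrum)
        if e <= 0:
            raise ValueError("electron energy must be positive")
    return ParticleState("electron", np.asarray(position, float),
                         direction, e)


# Secondary-electron source lines: the principal spectrum up to the
# 612 keV group. The weak lines above it (~0.3% intensity) would give
# electrons beyond the 432 keV Compton edge of the 612 keV line, which
# defines the spectrum's kinematic support.
_SECONDARY_LINE_MAX = 0.62


def generate_secondary_spectrum(n_samples: int,
                                rng: np.random.Generator,
                                n_bins: int = 64) -> SpectrumHistogram:
    """Regenerate the spectrum of first-interaction secondary electrons
    set in motion in water by the Ir-192 gamma lines.

    Samples a gamma line by intensity, chooses Compton vs photoelectric
    by the water cross-section ratio, and records the electron energy
    (Klein–Nishina sampling for Compton; the full photon energy for
    photoelectric). Support is [0, 432 keV]; the rare photoelectric
    events above the Compton edge are excluded.
    """
    if n_samples < 10**5:
        raise ValueError("n_samples must be >= 1e5 for a stable spectrum")
    water = mat.get_material("water")
    lines = [(e, i) for e, i in ir192_lines() if e <= _SECONDARY_LINE_MAX]
    energies = np.array([e for e, _ in lines])
    intens = np.array([i for _, i in lines])
    # per-line interaction probability ∝ intensity × total cross section
    sig = np.array([mat.photon_cross_sections(water, e).sigma_total
                    for e in energies])
    p_line = intens * sig
    p_line /= p_line.sum()
    pe_frac = np.array([
        mat.photon_cross_sections(water, e).sigma_photoelectric /
        mat.photon_cross_sections(water, e).sigma_total
        for e in energies])
    e_max = mat.compton_edge(energies.max())
    line_idx = rng.choice(len(energies), size=n_samples, p=p_line)
    out = np.empty(n_samples)
    n_out = 0
    for li in line_idx:
        e_gamma = energies[li]
        if rng.random() < pe_frac[li]:
            e_el = e_gamma  # photoelectric: full transfer (binding ignored)
        else:
            _, _, e_el, _ = mat.sample_compton(e_gamma, rng)
        if e_el <= e_max:
            out[n_out] = e_el
            n_out += 1
    counts, edges = np.histogram(out[:n_out], bins=n_bins, range=(0.0, e_max))
    return SpectrumHistogram(edges, counts / counts.sum())


@dataclass(frozen=True)
class SeedGeometry:
    """VS2000-style HDR seed: iridium core in a Ti-Ni casing [mm]."""

    length: float = 6.59
    diameter: float = 0.59
    core_radius: float = 0.17
    core_half_length: float = 2.5  # two 2.5 mm cylinders end-to-end
    endcap_radius: float = 0.295
    casing_material: str = "tini_44_56"
    core_material: str = "iridium"
    stub_length: float = 2.0  # drive-wire stub on the -axis side

    def __post_init__(self):
        if self.core_radius >= self.diameter / 2:
            raise ValueError("core does not fit inside casing")
        if 2 * self.core_half_length >= self.length:
            raise ValueError("core longer than casing")

    @property
    def active_length_cm(self) -> float:
        return 2 * self.core_half_length / 10.0

    @property
    def casing_half_length(self) -> float:
        return self.length / 2.0


@dataclass
class SeedPlan:
    """Weighted dwell positions of a single-catheter plan.

    Positions in cm (global frame); ``angle_deg`` is the seed-axis angle
    from the +y axis in the xy-plane; weights are dwell-time multiples.
    Defaults reproduce the 4-position, 20 Gy lung plan.
    """

    positions_cm: np.ndarray = field(default_factory=lambda: np.array([
        [4.423, 2.012, -0.141],
        [4.095, 2.630, -0.141],
        [3.766, 3.248, -0.141],
        [3.437, 3.866, -0.141],
    ]))
    weights: np.ndarray = field(default_factory=lambda: np.array(
        [1.370, 2.518, 1.296, 1.000]))
    angle_deg: float = -152.0
    prescription_gy: float = 20.0

    def __post_init__(self):
        self.positions_cm = np.atleast_2d(np.asarray(self.positions_cm, float))
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        if len(self.weights) != len(self.positions_cm):
            raise ValueError("one weight per position required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        if self.weights.sum() <= 0:
            raise ValueError("all-zero weights")

    @property
    def axis(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        return np.array([math.sin(a), math.cos(a), 0.0])

    def history_shares(self) -> np.ndarray:
        """Fraction of histories each dwell position receives."""
        return self.weights / self.weights.sum()

    def to_config(self) -> str:
        lines = [f"angle_deg = {self.angle_deg}",
                 f"prescription_gy = {self.prescription_gy}"]
        for p, w in zip(self.positions_cm, self.weights):
            lines.append(f"position = {p[0]},{p[1]},{p[2]},{w}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SeedPlan":
        positions, weights = [], []
        angle = -152.0
        rx = 20.0
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "angle_deg":
                angle = float(val)
            elif key == "prescription_gy":
                rx = float(val)
            elif key == "position":
                x, y, z, w = (float(v) for v in val.split(","))
                positions.append([x, y, z])
                weights.append(w)
        return cls(np.array(positions), np.array(weights), angle, rx)


def _line_arrays():
    lines = ir192_lines()
    e = np.array([l[0] for l in lines])
    i = np.array([l[1] for l in lines])
    cdf = np.cumsum(i) / i.sum()
    return e, cdf


_XS_ROW_CACHE: dict = {}


def _seed_xs_rows(tables: PhysicsTables, geometry: SeedGeometry):
    """(1, nE) total cross-section rows for core and casing materials."""
    core = mat.get_material(geometry.core_material)
    case = mat.get_material(geometry.casing_material)

    def row(material):
        key = (id(tables), material.name)
        if key not in _XS_ROW_CACHE:
            kn = np.array([mat.klein_nishina_total(e)
                           for e in tables.egrid])
            sig_c = kn * material.electrons_per_gram
            sig_p = np.array([mat.photoelectric_xs(material, e)
                              for e in tables.egrid])
            _XS_ROW_CACHE[key] = (sig_c + sig_p)[None, :]
        return _XS_ROW_CACHE[key]

    return row(core), core.density, row(case), case.density


_DEFAULT_TABLES: PhysicsTables | None = None


def _default_tables() -> PhysicsTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = PhysicsTables(("water",))
    return _DEFAULT_TABLES


def emit_seed_photon(geometry: SeedGeometry, center_mm, axis,
                     rng_seed: int = 0, casing: bool = True,
                     tables: PhysicsTables | None = None):
    """Emit one photon from the encapsulated seed (API wrapper).

    Returns ``(state_or_None, emission_energy)``; None means the photon
    was absorbed within the seed (first-flight attenuation; in-seed
    scatter is treated as absorption).
    """
    from .transport import ParticleState

    tables = tables or _default_tables()
    sig_ir, rho_ir, sig_tn, rho_tn = _seed_xs_rows(tables, geometry)
    line_e, line_cdf = _line_arrays()
    st = K.rng_state(rng_seed, 0)
    c = np.asarray(center_mm, float)
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    alive, x, y, z, dx, dy, dz, e = K.sample_seed_photon(
        c[0], c[1], c[2], a[0], a[1], a[2],
        geometry.core_radius, geometry.core_half_length,
        geometry.diameter / 2, geometry.casing_half_length,
        geometry.stub_length,
        line_e, line_cdf, sig_ir, sig_tn, rho_ir, rho_tn,
        tables.loge0, tables.dloge, 1 if casing else 0, st)
    if not alive:
        return None, e
    return ParticleState("photon", np.array([x, y, z]),
                         np.array([dx, dy, dz]), e), e


class PointElectronSource:
    """Isotropic point electron source, monoenergetic or spectral."""

    def __init__(self, position_mm, energy: float | None = None,
                 spectrum: SpectrumHistogram | None = None):
        if (energy is None) == (spectrum is None):
            raise ValueError("give exactly one of energy or spectrum")
        self.position = np.asarray(position_mm, float)
        self.energy = energy
        self.spectrum = spectrum

    def describe(self) -> str:
        if self.spectrum is not None:
            return f"point electron spectrum source at {self.position.tolist()}"
        return (f"point electron {self.energy} MeV source at "
                f"{self.position.tolist()}")

    def _run_batch(self, n, matidx, density, ox, oy, oz, sx, sy, sz,
                   bx, by, bz, tables, params, edep, seed, stream):
        if self.spectrum is not None:
            edges = self.spectrum.bin_edges
            cdf = np.cumsum(self.spectrum.probabilities)
            cdf /= cdf[-1]
            use_spec, mono = 1, 0.0
        else:
            edges = np.array([0.0, 1.0])
            cdf = np.array([1.0])
            use_spec, mono = 0, float(self.energy)
        scol_eff, n_hard, dcut, delta_on = tables.electron_loss_arrays(
            params.delta_rays, params.delta_range_cut)
        return K.run_point_electron_batch(
            n, self.position[0], self.position[1], self.position[2],
            mono, edges, cdf, use_spec,
            matidx, density, ox, oy, oz, sx, sy, sz, bx, by, bz,
            scol_eff, tables.range_g, tables.inv_x0,
            tables.loge0, tables.dloge,
            params.dr_over_range, params.final_range / 1000.0,
            params.electron_cutoff / 1000.0, params.max_step,
            params.chord_tolerance, 1 if params.scattering else 0,
            delta_on, n_hard, dcut,
            1 if params.straggling else 0, tables.zoa,
            edep, seed, stream)


class SeedPlanSource:
    """Weighted multi-dwell seed plan source for in-phantom runs."""

    def __init__(self, plan: SeedPlan,
                 geometry: SeedGeometry | None = None,
                 casing: bool = True):
        self.plan = plan
        self.geometry = geometry or SeedGeometry()
        self.casing = casing

    def describe(self) -> str:
        return (f"seed plan: {len(self.plan.weights)} dwell positions, "
                f"angle {self.plan.angle_deg} deg")

    def _run_batch(self, n, matidx, density, ox, oy, oz, sx, sy, sz,
                   bx, by, bz, tables, params, edep, seed, stream):
        g = self.geometry
        sig_ir, rho_ir, sig_tn, rho_tn = _seed_xs_rows(tables, g)
        line_e, line_cdf = _line_arrays()
        pos = self.plan.positions_cm * 10.0  # cm → mm
        axis = self.plan.axis
        axes = np.tile(axis, (len(pos), 1))
        w = self.plan.weights
        active = w > 0
        cdf_w = np.cumsum(w) / w.sum()
        mu_maj = tables.majorant(density, matidx)
        scol_eff, n_hard, dcut, delta_on = tables.electron_loss_arrays(
            params.delta_rays, params.delta_range_cut)
        emitted, dep, esc, absorbed = K.run_seed_plan_batch(
            n, np.ascontiguousarray(pos), np.ascontiguousarray(axes),
            cdf_w, g.core_radius, g.core_half_length, g.diameter / 2,
            g.casing_half_length, g.stub_length,
            line_e, line_cdf, sig_ir, sig_tn, rho_ir, rho_tn,
            1 if self.casing else 0,
            matidx, density, ox, oy, oz, sx, sy, sz, bx, by, bz,
            scol_eff, tables.range_g, tables.inv_x0,
            tables.sig_total, tables.sig_pe, mu_maj,
            tables.loge0, tables.dloge,
            params.dr_over_range, params.final_range / 1000.0,
            params.electron_cutoff / 1000.0, params.max_step,
            params.chord_tolerance, 1 if params.scattering else 0,
            delta_on, n_hard, dcut,
            1 if params.straggling else 0, tables.zoa,
            params.photon_cutoff / 1000.0, edep, seed, stream)
        resid = abs(emitted - dep - esc - absorbed) / max(n, 1)
        return emitted, dep, esc, absorbed, resid


def combine_plan_doses(doses: list[DoseGrid], weights) -> DoseGrid:
    """Algebraic weighted combination Σ wᵢ·Dᵢ of per-dwell dose grids.

    Exactly linear in the weights (doubling every weight doubles each
    voxel). Use when per-dwell grids were scored separately.
    """
    weights = np.asarray(weights, float)
    if len(weights) != len(doses):
        raise ValueError("one weight per dose grid required")
    out = doses[0].scaled(weights[0])
    for d, w in zip(doses[1:], weights[1:]):
        if not out.same_geometry(d):
            raise ValueError("dose grid geometries differ")
        out.mean = out.mean + d.mean * w
        out.sem = np.sqrt(out.sem**2 + (d.sem * w) ** 2)
    return out


def run_plan(plan: SeedPlan, phantom: VoxelPhantom, fieldspec,
             params, n_histories: int, seed: int,
             n_batches: int = 10,
             geometry: SeedGeometry | None = None) -> DoseGrid:
    """Simulate a weighted dwell plan; dwell positions receive histories
    in proportion to their weights."""
    from .transport import run_histories

    if len(plan.weights) < 1:
        raise ValueError("plan needs at least one position")
    src = SeedPlanSource(plan, geometry)
    return run_histories(src, phantom, fieldspec, params, n_histories,
                         n_batches=n_batches, seed=seed)
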