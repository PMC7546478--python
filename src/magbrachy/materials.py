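"""Material definitions and the electron/photon physics data layer.

The engine deliberately uses compact, documented models rather than a full
cross-section library:

* electron mass collision stopping power — Berger–Seltzer formula (no
  density-effect correction; < 2% below 1 MeV in low-Z media),
* CSDA range — numerical quadrature of 1/S_col,
* multiple scattering — Highland's Gaussian small-angle width,
* Compton — free-electron Klein–Nishina (total cross section and sampler),
* photoelectric — a Z^4.5/E^3 parametrization anchored in water,
* Rayleigh — optional, off by default (returns zero),
* air mass energy-absorption coefficients — embedded reference table.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np

from .constants import (
    ELECTRON_MASS_MEV,
    ELEMENTS,
    N_AVOGADRO,
    R_ELECTRON_CM,
)

# Supported kinetic-energy ranges [MeV]
E_MIN_ELECTRON = 1e-3
E_MAX_ELECTRON = 2.0
E_MIN_PHOTON = 5e-3
E_MAX_PHOTON = 1.0

_SIGMA_T = 8.0 * math.pi / 3.0 * R_ELECTRON_CM**2  # Thomson cross section, cm²


class EnergyRangeError(ValueError):
    """Requested energy outside the supported tabulation range."""


@dataclass(frozen=True)
class ElementFraction:
    Z: int
    A: float
    weight_fraction: float

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if not (0.0 < self.weight_fraction <= 1.0):
            raise ValueError(
                f"weight fraction must be in (0, 1], got {self.weight_fraction}"
            )


@dataclass(frozen=True)
class Material:
    """A homogeneous material: composition, bulk density and I-value."""

    name: str
    density: float  # g/cm³
    composition: tuple[ElementFraction, ...]
    mean_excitation_energy: float  # eV

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.mean_excitation_energy <= 0:
            raise ValueError("mean excitation energy must be positive")
        total = sum(f.weight_fraction for f in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"composition fractions of {self.name!r} sum to {total}, not 1"
            )

    @property
    def electrons_per_gram(self) -> float:
        return N_AVOGADRO * sum(
            f.weight_fraction * f.Z / f.A for f in self.composition
        )

    @property
    def z_over_a(self) -> float:
        return sum(f.weight_fraction * f.Z / f.A for f in self.composition)

    @property
    def radiation_length(self) -> float:
        """Radiation length X0 in g/cm² (Tsai/PDG approximation, mass-mixed)."""
        inv = 0.0
        for f in self.composition:
            x0_i = 716.408 * f.A / (
                f.Z * (f.Z + 1.0) * math.log(287.0 / math.sqrt(f.Z))
            )
            inv += f.weight_fraction / x0_i
        return 1.0 / inv


@dataclass(frozen=True)
class PhotonXS:
    energy: float  # MeV
    sigma_compton: float  # cm²/g
    sigma_photoelectric: float  # cm²/g
    sigma_rayleigh: float  # cm²/g

    @property
    def sigma_total(self) -> float:
        return self.sigma_compton + self.sigma_photoelectric + self.sigma_rayleigh


def _comp(pairs: dict[str, float]) -> tuple[ElementFraction, ...]:
    out = []
    for sym, w in pairs.items():
        Z, A, _ = ELEMENTS[sym]
        out.append(ElementFraction(Z, A, w))
    return tuple(out)


def _bragg_I(pairs: dict[str, float]) -> float:
    """Bragg-additivity mean excitation energy for a mixture [eV]."""
    num = 0.0
    den = 0.0
    for sym, w in pairs.items():
        Z, A, I = ELEMENTS[sym]
        num += w * Z / A * math.log(I)
        den += w * Z / A
    return math.exp(num / den)


# ICRP adult-lung elemental composition (as shipped with common MC codes).
_LUNG_COMP = {
    "H": 0.101278, "C": 0.102310, "N": 0.028650, "O": 0.757072,
    "Na": 0.001840, "Mg": 0.000730, "P": 0.000800, "S": 0.002250,
    "Cl": 0.002660, "K": 0.001940, "Ca": 0.000090, "Fe": 0.000370,
    "Zn": 0.000010,
}
_MUSCLE_COMP = {
    "H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710,
    "Na": 0.001, "P": 0.002, "S": 0.003, "Cl": 0.001, "K": 0.004,
}
_AIR_COMP = {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827}
_TINI_COMP = {"Ti": 0.44, "Ni": 0.56}

BUILTIN_MATERIALS: dict[str, Material] = {
    "water": Material("water", 1.0, _comp({"H": 0.111894, "O": 0.888106}), 75.0),
    "lung_icrp": Material("lung_icrp", 0.26, _comp(_LUNG_COMP), 75.3),
    "air": Material("air", 1.2048e-3, _comp(_AIR_COMP), 85.7),
    "muscle_icrp": Material("muscle_icrp", 1.05, _comp(_MUSCLE_COMP), 75.3),
    "tini_44_56": Material("tini_44_56", 6.5, _comp(_TINI_COMP), _bragg_I(_TINI_COMP)),
    "iridium": Material("iridium", 22.42, _comp({"Ir": 1.0}), 757.0),
    # Vacuum: token composition, vanishing density; the transport engine
    # treats any density below 1e-6 g/cm³ as non-interacting.
    "vacuum": Material("vacuum", 1e-25, _comp({"H": 1.0}), 19.2),
}


def get_material(name: str) -> Material:
    try:
        return BUILTIN_MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; built-ins: {sorted(BUILTIN_MATERIALS)}"
        ) from None


def material_from_config(text: str) -> Material:
    """Parse a material from a text config block.

    Format (one key per line)::

        name = mystuff
        density = 1.2
        I = 75.0
        elements = H:0.1119, O:0.8881
    """
    kv = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        k, _, v = line.partition("=")
        kv[k.strip().lower()] = v.strip()
    pairs = {}
    for item in kv["elements"].split(","):
        sym, _, w = item.partition(":")
        pairs[sym.strip()] = float(w)
    I = float(kv["i"]) if "i" in kv else _bragg_I(pairs)
    return Material(kv["name"], float(kv["density"]), _comp(pairs), I)


# ---------------------------------------------------------------------------
# Electron physics
# ---------------------------------------------------------------------------

def collision_stopping_power(material: Material, energy: float) -> float:
    """Berger–Seltzer mass collision stopping power [MeV·cm²/g].

    No density-effect or shell corrections; valid for the package's
    1 keV–2 MeV electron transport window.
    """
    if not (E_MIN_ELECTRON <= energy <= E_MAX_ELECTRON):
        raise EnergyRangeError(
            f"electron energy {energy} MeV outside "
            f"[{E_MIN_ELECTRON}, {E_MAX_ELECTRON}] MeV"
        )
    tau = energy / ELECTRON_MASS_MEV
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    i_ratio = material.mean_excitation_energy * 1e-6 / ELECTRON_MASS_MEV
    ln_term = math.log(tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio))
    f_minus = (
        1.0
        - beta2
        + (tau * tau / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / (gamma * gamma)
    )
    return 0.153536 / beta2 * material.z_over_a * (ln_term + f_minus)


def restricted_stopping_power(material: Material, energy: float,
                              delta_cut: float) -> float:
    """Berger–Seltzer collision stopping power restricted to soft
    collisions (energy transfers below ``delta_cut`` [MeV]).

    Used when δ-ray production is enabled: transfers above the cut are
    sampled as discrete Møller collisions instead. Equals the full
    stopping power when delta_cut ≥ E/2 (the Møller maximum transfer).
    """
    if delta_cut >= energy / 2.0:
        return collision_stopping_power(material, energy)
    if not (E_MIN_ELECTRON <= energy <= E_MAX_ELECTRON):
        raise EnergyRangeError("electron energy outside supported range")
    tau = energy / ELECTRON_MASS_MEV
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    eta = delta_cut / energy
    i_ratio = material.mean_excitation_energy * 1e-6 / ELECTRON_MASS_MEV
    ln_term = math.log(tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio))
    g_minus = (
        -1.0 - beta2
        + math.log(4.0 * (1.0 - eta) * eta)
        + 1.0 / (1.0 - eta)
        + (1.0 - beta2)
        * (tau * tau * eta * eta / 2.0 + (2.0 * tau + 1.0) * math.log(1.0 - eta))
    )
    return 0.153536 / beta2 * material.z_over_a * (ln_term + g_minus)


def moller_hard_collision_density(material: Material, energy: float,
                                  delta_cut: float) -> float:
    """Number of Møller collisions with transfer > delta_cut per g/cm²."""
    if delta_cut >= energy / 2.0:
        return 0.0
    tau = energy / ELECTRON_MASS_MEV
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    g1 = (tau / gamma) ** 2
    g2 = (2.0 * tau + 1.0) / (gamma * gamma)
    eta = delta_cut / energy
    eps = np.linspace(eta, 0.5, 2000)
    m = (1.0 / eps**2 + 1.0 / (1.0 - eps) ** 2 + g1
         - g2 / (eps * (1.0 - eps)))
    integral = np.trapezoid(m, eps)
    return 0.153536 / beta2 * material.z_over_a / energy * float(integral)


_RANGE_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _range_table(material: Material) -> tuple[np.ndarray, np.ndarray]:
    key = material.name
    if key not in _RANGE_CACHE:
        egrid = np.logspace(
            math.log10(E_MIN_ELECTRON), math.log10(E_MAX_ELECTRON), 1200
        )
        s = np.array([collision_stopping_power(material, e) for e in egrid])
        inv = 1.0 / s
        r = np.concatenate(
            ([0.0], np.cumsum(0.5 * (inv[1:] + inv[:-1]) * np.diff(egrid)))
        )
        # Residual range below the 1 keV grid floor, approximated by a
        # constant stopping power from 0 to 1 keV.
        r += egrid[0] / s[0]
        _RANGE_CACHE[key] = (egrid, r)
    return _RANGE_CACHE[key]


def csda_range(material: Material, energy: float) -> float:
    """CSDA range r(E) = ∫ dE'/S_col(E') in g/cm² (mass thickness)."""
    if not (E_MIN_ELECTRON <= energy <= E_MAX_ELECTRON):
        raise EnergyRangeError(
            f"electron energy {energy} MeV outside supported range"
        )
    egrid, r = _range_table(material)
    return float(np.interp(math.log(energy), np.log(egrid), r))


def scattering_sigma(material: Material, energy: float, step_length: float) -> float:
    """Highland Gaussian multiple-scattering width θ0 [rad] over a step [cm]."""
    if step_length <= 0:
        raise ValueError("step_length must be positive")
    if not (E_MIN_ELECTRON <= energy <= E_MAX_ELECTRON):
        raise EnergyRangeError("energy outside supported electron range")
    x = step_length * material.density
    t = x / material.radiation_length
    if t >= 1.0:
        raise ValueError(
            f"step of {t:.2f} radiation lengths too long for the "
            "small-angle Highland model"
        )
    pc = math.sqrt(energy * (energy + 2.0 * ELECTRON_MASS_MEV))
    beta = pc / (energy + ELECTRON_MASS_MEV)
    corr = 1.0 + 0.038 * math.log(t)
    theta0 = 13.6 / (beta * pc) * math.sqrt(t) * corr
    return max(theta0, 0.0)


# ---------------------------------------------------------------------------
# Photon physics
# ---------------------------------------------------------------------------

def klein_nishina_total(energy: float) -> float:
    """Total Klein–Nishina cross section per electron [cm²]."""
    k = energy / ELECTRON_MASS_MEV
    t1 = (1.0 + k) / (k * k) * (
        2.0 * (1.0 + k) / (1.0 + 2.0 * k) - math.log(1.0 + 2.0 * k) / k
    )
    t2 = math.log(1.0 + 2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return 2.0 * math.pi * R_ELECTRON_CM**2 * (t1 + t2 - t3)


_PE_ANCHOR_E = 0.026  # MeV; in water σ_pe is taken equal to σ_KN here
_PE_EXPONENT = 4.5
_PE_CONST: float | None = None


def _pe_constant() -> float:
    global _PE_CONST
    if _PE_CONST is None:
        water = BUILTIN_MATERIALS["water"]
        target = klein_nishina_total(_PE_ANCHOR_E) * water.electrons_per_gram
        raw = sum(
            f.weight_fraction * N_AVOGADRO / f.A * f.Z**_PE_EXPONENT
            for f in water.composition
        )
        _PE_CONST = target / raw
    return _PE_CONST


def photoelectric_xs(material: Material, energy: float) -> float:
    """Parametrized photoelectric mass attenuation coefficient [cm²/g].

    τ/ρ = C · Σ_i w_i (N_A/A_i) Z_i^4.5 · (E_anchor/E)³ with C calibrated
    so that in water the photoelectric and Klein–Nishina Compton
    components cross at 26 keV. Deliberately coarse: photoelectric
    absorption is a sub-percent channel in tissue at Ir-192 energies.
    """
    c = _pe_constant()
    raw = sum(
        f.weight_fraction * N_AVOGADRO / f.A * f.Z**_PE_EXPONENT
        for f in material.composition
    )
    return c * raw * (_PE_ANCHOR_E / energy) ** 3


def photon_cross_sections(
    material: Material, energy: float, include_rayleigh: bool = False
) -> PhotonXS:
    """Photon interaction coefficients [cm²/g] at a given energy."""
    if not (E_MIN_PHOTON <= energy <= E_MAX_PHOTON):
        raise EnergyRangeError(
            f"photon energy {energy} MeV outside "
            f"[{E_MIN_PHOTON}, {E_MAX_PHOTON}] MeV (5 keV tracking cutoff)"
        )
    compton = klein_nishina_total(energy) * material.electrons_per_gram
    pe = photoelectric_xs(material, energy)
    ray = 0.0  # optional channel, disabled in this build
    return PhotonXS(energy, compton, pe, ray)


def compton_edge(energy: float) -> float:
    """Maximum Compton electron energy 2E²/(m_e c² + 2E) [MeV]."""
    return 2.0 * energy * energy / (ELECTRON_MASS_MEV + 2.0 * energy)


def sample_compton(energy: float, rng: np.random.Generator):
    """Sample a free-electron Klein–Nishina Compton event.

    Returns ``(scattered_E, photon_angle, electron_E, electron_angle)``
    with energies in MeV and polar angles in radians relative to the
    incident photon direction. Electron binding is ignored, so energy
    conservation E = E' + E_e holds exactly per sample.
    """
    if energy < E_MIN_PHOTON:
        raise EnergyRangeError("photon below the 5 keV tracking cutoff")
    k = energy / ELECTRON_MASS_MEV
    eps_min = 1.0 / (1.0 + 2.0 * k)
    a1 = math.log(1.0 / eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if rng.random() * (a1 + a2) < a1:
            eps = math.exp(-a1 * rng.random())
        else:
            eps = math.sqrt(eps_min * eps_min + rng.random() * (1.0 - eps_min**2))
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if rng.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            break
    cos_theta = 1.0 - t
    e_scat = eps * energy
    e_el = energy - e_scat
    theta = math.acos(max(-1.0, min(1.0, cos_theta)))
    if e_el > 0:
        p_el = math.sqrt(e_el * (e_el + 2.0 * ELECTRON_MASS_MEV))
        cos_el = (energy - e_scat * cos_theta) / p_el
        cos_el = max(-1.0, min(1.0, cos_el))
        theta_el = math.acos(cos_el)
    else:
        theta_el = 0.0
    return e_scat, theta, e_el, theta_el


# ---------------------------------------------------------------------------
# Air mass energy-absorption coefficients
# ---------------------------------------------------------------------------

_MU_EN_TABLE: tuple[np.ndarray, np.ndarray] | None = None


def _mu_en_table() -> tuple[np.ndarray, np.ndarray]:
    global _MU_EN_TABLE
    if _MU_EN_TABLE is None:
        path = importlib.resources.files("magbrachy.data") / "mu_en_air.csv"
        arr = np.loadtxt(str(path), delimiter=",", comments="#")
        _MU_EN_TABLE = (arr[:, 0], arr[:, 1])
    return _MU_EN_TABLE


def mu_en_air(energy: float) -> float:
    """Air mass energy-absorption coefficient μ_en/ρ [cm²/g], log-log interp."""
    e, mu = _mu_en_table()
    if not (e[0] <= energy <= e[-1]):
        raise EnergyRangeError(
            f"energy {energy} MeV outside the air μ_en/ρ table "
            f"[{e[0]}, {e[-1]}] MeV"
        )
    return float(
        np.exp(np.interp(np.log(energy), np.log(e), np.log(mu)))
    )


def mean_compton_electron_fraction(energy: float) -> float:
    """Mean fraction of photon energy given to the Compton electron.

    Integrates the Klein–Nishina differential cross section in the
    scattered-energy variable (64-point Gauss–Legendre quadrature).
    """
    k = energy / ELECTRON_MASS_MEV
    eps_min = 1.0 / (1.0 + 2.0 * k)
    x, w = np.polynomial.legendre.leggauss(64)
    eps = 0.5 * (x + 1.0) * (1.0 - eps_min) + eps_min
    ww = w * 0.5 * (1.0 - eps_min)
    # dσ/dε ∝ (1/ε + ε − sin²θ) with sin²θ = t(2−t), t = (1−ε)/(kε)
    t = (1.0 - eps) / (k * eps)
    sin2 = t * (2.0 - t)
    f = 1.0 / eps + eps - sin2
    norm = np.sum(ww * f)
    mean_eps = np.sum(ww * f * eps) / norm
    return float(1.0 - mean_eps)


def energy_transfer_coefficient(material: Material, energy: float) -> float:
    """Mass energy-transfer coefficient μ_tr/ρ [cm²/g] from the model's
    own channels (Compton electron share + photoelectric)."""
    xs = photon_cross_sections(material, energy)
    return (
        xs.sigma_compton * mean_compton_electron_fraction(energy)
        + xs.sigma_photoelectric
    )
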