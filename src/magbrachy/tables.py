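"""Dense per-material physics tables consumed by the transport kernels.

All electron/photon quantities are pre-evaluated on a shared log-spaced
energy grid so the kernels only ever do linear interpolation in log(E).
"""

from __future__ import annotations

import math

import numpy as np

from . import materials as mat

N_NODES = 400


class PhysicsTables:
    """Arrays of stopping power, CSDA range, X0 and photon coefficients.

    One row per material, aligned with the phantom's material indices.
    ``mu_tr`` (mass energy-transfer coefficient) is built on demand.
    """

    def __init__(self, material_names: tuple[str, ...]):
        self.material_names = tuple(material_names)
        mats = [mat.get_material(n) for n in material_names]
        self.materials = mats
        self.egrid = np.logspace(
            math.log10(mat.E_MIN_ELECTRON), math.log10(mat.E_MAX_ELECTRON), N_NODES
        )
        self.loge0 = math.log(self.egrid[0])
        self.dloge = math.log(self.egrid[1]) - math.log(self.egrid[0])
        nm = len(mats)
        self.scol = np.zeros((nm, N_NODES))
        self.range_g = np.zeros((nm, N_NODES))
        self.inv_x0 = np.zeros(nm)
        self.sig_compton = np.zeros((nm, N_NODES))
        self.sig_pe = np.zeros((nm, N_NODES))
        self.sig_total = np.zeros((nm, N_NODES))
        self._mu_tr: np.ndarray | None = None
        self._delta_cut_mm: float | None = None
        self.zoa = np.array([m.z_over_a if m.density >= 1e-6 else 0.0
                             for m in mats])
        for m, material in enumerate(mats):
            if material.density < 1e-6:  # vacuum: non-interacting
                self.range_g[m, :] = 1e30
                continue
            self.scol[m] = [
                mat.collision_stopping_power(material, e) for e in self.egrid
            ]
            self.range_g[m] = [mat.csda_range(material, e) for e in self.egrid]
            self.inv_x0[m] = 1.0 / material.radiation_length
            kn = np.array([mat.klein_nishina_total(e) for e in self.egrid])
            self.sig_compton[m] = kn * material.electrons_per_gram
            self.sig_pe[m] = [
                mat.photoelectric_xs(material, e) for e in self.egrid
            ]
            self.sig_total[m] = self.sig_compton[m] + self.sig_pe[m]

    def build_delta(self, range_cut_mm: float = 0.05) -> None:
        """Build restricted stopping power and hard-collision tables for
        δ-ray production with the given range cut.

        The per-material energy threshold is the kinetic energy whose
        CSDA geometric range equals ``range_cut_mm`` in that material.
        """
        if self._delta_cut_mm == range_cut_mm:
            return
        self._delta_cut_mm = range_cut_mm
        nm = len(self.materials)
        self.delta_cut_e = np.zeros(nm)
        self.l_delta = self.scol.copy()
        self.n_hard = np.zeros((nm, N_NODES))
        for m, material in enumerate(self.materials):
            if material.density < 1e-6:
                continue
            grammage = range_cut_mm / 10.0 * material.density
            cut = float(np.interp(grammage, self.range_g[m], self.egrid))
            cut = max(cut, self.egrid[0])
            self.delta_cut_e[m] = cut
            self.l_delta[m] = [
                mat.restricted_stopping_power(material, e, cut)
                for e in self.egrid
            ]
            self.n_hard[m] = [
                mat.moller_hard_collision_density(material, e, cut)
                for e in self.egrid
            ]

    def electron_loss_arrays(self, delta_on: bool, range_cut_mm: float):
        """(continuous-loss table, hard-collision table, per-material δ
        threshold, flag) — restricted tables when δ production is on."""
        if delta_on:
            self.build_delta(range_cut_mm)
            return self.l_delta, self.n_hard, self.delta_cut_e, 1
        nm = len(self.materials)
        return self.scol, np.zeros((nm, 1)), np.zeros(nm), 0

    @property
    def mu_tr(self) -> np.ndarray:
        if self._mu_tr is None:
            frac = np.array(
                [mat.mean_compton_electron_fraction(e) for e in self.egrid]
            )
            self._mu_tr = self.sig_compton * frac[None, :] + self.sig_pe
        return self._mu_tr

    def index_of(self, name: str) -> int:
        return self.material_names.index(name)

    def majorant(self, density: np.ndarray, material_index: np.ndarray) -> np.ndarray:
        """Per-energy-node majorant attenuation [1/cm] over a phantom."""
        nm = len(self.materials)
        rho_max = np.zeros(nm)
        for m in range(nm):
            sel = material_index == m
            if np.any(sel):
                rho_max[m] = float(density[sel].max())
        return np.max(self.sig_total * rho_max[:, None], axis=0)
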