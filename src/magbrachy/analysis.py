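"""Everything downstream of the dose grids: normalization, iso-dose
radial distances, dose-difference maps with significance masking, and
cumulative DVH curves and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid


class AnalysisError(ValueError):
    pass


@dataclass
class IsoDoseProfile:
    """Radial distance of one iso-dose level along source-axis rays."""

    level: float  # % of the normalization dose
    distances: dict  # direction label -> mm
    mean: float  # mm
    sem: float  # mm
    at_edge: bool = False  # level still above threshold at the grid edge

    def __post_init__(self):
        if not (0.0 < self.level <= 100.0):
            raise ValueError("level must be in (0, 100]")


@dataclass
class DVHResult:
    bin_edges: np.ndarray  # % of prescription
    cum_volume: np.ndarray  # %, non-increasing
    v90: float
    v100: float
    v150: float
    v200: float
    d90: float  # % of prescription
    d100: float
    d2cc: float | None = None

    def to_csv(self, path):
        np.savetxt(path, np.column_stack([self.bin_edges[:-1],
                                          self.cum_volume]),
                   delimiter=",", comments="",
                   header="dose_percent_of_rx,volume_percent")


def normalize_at_point(dose: DoseGrid, point_mm,
                       max_ref_sem: float = 0.05) -> DoseGrid:
    """Normalize a dose grid to 100% at a reference point.

    The reference value is the mean over the 3×3×3 voxel neighborhood
    of the voxel containing ``point_mm`` (suppresses single-voxel MC
    noise). Raises if the reference is zero or its relative SEM exceeds
    ``max_ref_sem``.
    """
    i, j, k = dose.voxel_of(point_mm)
    nx, ny, nz = dose.dims
    sl = (slice(max(i - 1, 0), min(i + 2, nx)),
          slice(max(j - 1, 0), min(j + 2, ny)),
          slice(max(k - 1, 0), min(k + 2, nz)))
    ref = float(dose.mean[sl].mean())
    if ref <= 0:
        raise AnalysisError("reference dose at the normalization point is 0")
    nvox = dose.mean[sl].size
    ref_sem = float(np.sqrt((dose.sem[sl] ** 2).sum())) / nvox
    if ref_sem / ref > max_ref_sem:
        raise AnalysisError(
            f"reference dose undersampled: SEM {100 * ref_sem / ref:.1f}% "
            f"exceeds {100 * max_ref_sem:.0f}%")
    out = dose.scaled(100.0 / ref, unit="% of reference")
    out.meta["normalization_point_mm"] = list(np.asarray(point_mm, float))
    out.meta["reference_value"] = ref
    return out


_DIRS = {"+x": (1, 0, 0), "-x": (-1, 0, 0),
         "+y": (0, 1, 0), "-y": (0, -1, 0),
         "+z": (0, 0, 1), "-z": (0, 0, -1)}


def _axis_profile(dose: DoseGrid, origin_mm, direction, tube_half: int = 1):
    """1D profile along an axis ray from the source, averaged over a
    (2·tube_half+1)²-voxel transverse tube. Returns (radii_mm, values)."""
    i0, j0, k0 = dose.voxel_of(origin_mm)
    nx, ny, nz = dose.dims
    step = np.array(direction)
    axis = int(np.nonzero(step)[0][0])
    sgn = int(step[axis])
    n_along = {0: nx, 1: ny, 2: nz}[axis]
    start = (i0, j0, k0)[axis]
    count = (n_along - 1 - start) if sgn > 0 else start
    radii = []
    values = []
    for s in range(count + 1):
        idx = [i0, j0, k0]
        idx[axis] = start + sgn * s
        sls = []
        for ax in range(3):
            if ax == axis:
                sls.append(slice(idx[ax], idx[ax] + 1))
            else:
                sls.append(slice(max(idx[ax] - tube_half, 0),
                                 idx[ax] + tube_half + 1))
        values.append(float(dose.mean[tuple(sls)].mean()))
        center = dose.origin[axis] + (idx[axis] + 0.5) * dose.spacing[axis]
        radii.append(abs(center - np.asarray(origin_mm, float)[axis]))
    return np.array(radii), np.array(values)


def _azimuthal_profile(dose: DoseGrid, origin_mm, slab_half: int = 1,
                       n_bins: int | None = None):
    """Azimuthally averaged radial profile in the z = source plane."""
    o = np.asarray(origin_mm, float)
    k0 = dose.voxel_of(o)[2]
    nx, ny, nz = dose.dims
    slab = dose.mean[:, :, max(k0 - slab_half, 0):k0 + slab_half + 1]
    slab = slab.mean(axis=2)
    x = dose.origin[0] + (np.arange(nx) + 0.5) * dose.spacing[0] - o[0]
    y = dose.origin[1] + (np.arange(ny) + 0.5) * dose.spacing[1] - o[1]
    r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
    rmax = min(abs(x[0]), x[-1], abs(y[0]), y[-1])
    if n_bins is None:
        n_bins = int(rmax / float(dose.spacing[0]))
    edges = np.linspace(0, rmax, n_bins + 1)
    idx = np.digitize(r.ravel(), edges) - 1
    vals = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            vals[b] = slab.ravel()[sel].mean()
    return 0.5 * (edges[:-1] + edges[1:]), vals


def _outermost_crossing(radii, values, level):
    """Outermost radius where the profile falls through ``level``,
    linearly interpolated. Returns (distance, at_edge)."""
    above = np.nonzero(values >= level)[0]
    if len(above) == 0:
        raise AnalysisError(f"level {level}% never reached on this ray")
    i = above[-1]
    if i + 1 >= len(values):
        return float(radii[i]), True
    v0, v1 = values[i], values[i + 1]
    r0, r1 = radii[i], radii[i + 1]
    if v0 == v1:
        return float(r0), False
    return float(r0 + (v0 - level) / (v0 - v1) * (r1 - r0)), False


def isodose_distance(dose_normalized: DoseGrid, level: float,
                     origin_mm=(0.0, 0.0, 0.0),
                     directions=("+x", "-x", "+y", "-y"),
                     mode: str = "axis") -> IsoDoseProfile:
    """Radial distance of an iso-dose level from the source.

    ``mode='axis'`` measures the outermost crossing along each requested
    axis ray (3-voxel-wide tube averaging) and reports mean ± SEM over
    directions; ``mode='azimuthal'`` uses the azimuthally averaged
    profile in the source plane (one distance, SEM from the crossing
    bin's spread).
    """
    if mode == "azimuthal":
        radii, vals = _azimuthal_profile(dose_normalized, origin_mm)
        d, at_edge = _outermost_crossing(radii, vals, level)
        return IsoDoseProfile(level, {"azimuthal": d}, d,
                              float(dose_normalized.spacing[0]) / 2,
                              at_edge)
    dists = {}
    at_edge = False
    for name in directions:
        radii, vals = _axis_profile(dose_normalized, origin_mm, _DIRS[name])
        d, edge = _outermost_crossing(radii, vals, level)
        dists[name] = d
        at_edge |= edge
    arr = np.array(list(dists.values()))
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return IsoDoseProfile(level, dists, float(arr.mean()), sem, at_edge)


def percent_reduction(profile_b0: IsoDoseProfile,
                      profile_b: IsoDoseProfile) -> tuple[float, float]:
    """Percent reduction of an iso-dose distance, 100·(1 − d_B/d_B0),
    with first-order SEM propagation. Returns (value, sem)."""
    if profile_b0.level != profile_b.level:
        raise AnalysisError("profiles have different iso-dose levels")
    a, b = profile_b0.mean, profile_b.mean
    val = 100.0 * (1.0 - b / a)
    sem = 100.0 * math.sqrt((profile_b.sem / a) ** 2 +
                            (b * profile_b0.sem / a**2) ** 2)
    return val, sem


def difference_map(dose_a: DoseGrid, dose_b: DoseGrid,
                   min_percent: float = 2.0) -> np.ndarray:
    """Relative difference map 100·(B−A)/A with significance masking.

    Voxels are NaN-masked where A is zero, where |difference| ≤
    ``min_percent`` or where |difference| does not exceed one combined
    standard deviation (σ propagated to the ratio).
    """
    if not dose_a.same_geometry(dose_b):
        raise AnalysisError("dose grid geometries differ")
    a = dose_a.mean
    b = dose_b.mean
    out = np.full(a.shape, np.nan)
    ok = a > 0
    diff = np.zeros_like(a)
    diff[ok] = 100.0 * (b[ok] - a[ok]) / a[ok]
    sig = np.zeros_like(a)
    sig[ok] = 100.0 * np.sqrt(
        dose_b.sem[ok] ** 2 + (b[ok] * dose_a.sem[ok] / a[ok]) ** 2) / a[ok]
    keep = ok & (np.abs(diff) > min_percent) & (np.abs(diff) > sig)
    out[keep] = diff[keep]
    return out


def compute_dvh(dose: DoseGrid, mask: np.ndarray, prescription: float,
                want_d2cc: bool = False,
                bin_percent: float = 0.5) -> DVHResult:
    """Cumulative DVH of a structure on the percent-of-prescription axis.

    Vx = % of structure volume receiving ≥ x% of the prescription;
    Dx = minimum dose (as % of prescription) received by the hottest x%
    of the volume (interpolated order statistic); D2cc = minimum dose to
    the hottest 2 cm³ (exact voxel-count ceiling).

    ``dose`` must be in the same absolute unit as ``prescription``.
    """
    if not np.any(mask):
        raise AnalysisError("empty structure mask")
    doses = dose.mean[mask].astype(float)
    pct = doses / prescription * 100.0
    top = max(pct.max(), 250.0)
    edges = np.arange(0.0, top + bin_percent, bin_percent)
    srt = np.sort(pct)
    cum = (1.0 - np.searchsorted(srt, edges[:-1], side="left") /
           len(srt)) * 100.0

    def vx(x):
        return float((pct >= x).mean() * 100.0)

    def dx(x):
        # dose to the hottest x% == (100-x)th percentile of the voxel doses
        return float(np.percentile(pct, 100.0 - x))

    d2cc = None
    if want_d2cc:
        vox = dose.voxel_volume_cm3
        n2 = int(math.ceil(2.0 / vox))
        if mask.sum() < n2:
            raise AnalysisError(
                "structure smaller than 2 cm³; D2cc undefined")
        part = np.partition(pct, len(pct) - n2)
        d2cc = float(part[len(pct) - n2])
    return DVHResult(edges, cum, vx(90), vx(100), vx(150), vx(200),
                     dx(90), dx(100), d2cc)


def normalize_to_prescription(dose: DoseGrid, ptv_mask: np.ndarray,
                              prescription: float = 20.0) -> DoseGrid:
    """Globally rescale a dose grid so that D90(PTV) equals the
    prescription (the standard interstitial prescription surrogate;
    the anchor choice is recorded in the grid metadata)."""
    if not np.any(ptv_mask):
        raise AnalysisError("empty PTV mask")
    d90 = float(np.percentile(dose.mean[ptv_mask], 10.0))
    if d90 <= 0:
        raise AnalysisError("PTV D90 is zero; cannot normalize")
    out = dose.scaled(prescription / d90, unit="Gy")
    out.meta["prescription_gy"] = prescription
    out.meta["normalization_anchor"] = "D90(PTV)"
    return out
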