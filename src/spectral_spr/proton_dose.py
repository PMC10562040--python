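"""Simplified analytic proton dose engine.

Desk-scale stand-in for a clinical pencil-beam engine: water-equivalent
path length (WEPL) by voxel-exact ray tracing through an SPR map, analytic
Bragg curves from a power-law range-energy relation R0 = alpha * E^p with
Gaussian range straggling, nonnegative-least-squares SOBP weighting to
cover a spherical PTV, parallel-beam dose grids with a Gaussian lateral
penumbra, and R90 range extraction from central-axis depth-dose profiles.

The engine reproduces comparison arithmetic and qualitative range behavior
between two SPR maps computed under identical settings; it makes no claim
to absolute clinical dosimetry (no spot optimization, nuclear halo or
Monte Carlo transport).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import nnls

from .segmentation_spr import SPRMap
from .spectral_calibration import round_half_away

__all__ = [
    "ALPHA_CM_PER_MEV_P",
    "P_EXPONENT",
    "BeamSpec",
    "PTVSphere",
    "DepthDoseProfile",
    "DoseGrid",
    "range_from_energy",
    "energy_from_range",
    "straggling_sigma_mm",
    "bragg_curve",
    "sobp_weights",
    "sobp_dose",
    "wepl_along_ray",
    "plan_beam",
    "compute_dose",
    "central_axis_profile",
    "r90_range",
    "range_comparison",
]

# Power-law range-energy parameterization (range in cm, energy in MeV).
ALPHA_CM_PER_MEV_P = 0.0022
P_EXPONENT = 1.77
# Gaussian range straggling sigma = 0.012 * R0^0.935 (both in cm).
STRAGGLING_COEF = 0.012
STRAGGLING_EXP = 0.935
ENERGY_BAND_MEV = (70.0, 230.0)


def range_from_energy(energy_mev: float) -> float:
    """Water range R0 in mm from the power-law range-energy relation."""
    return 10.0 * ALPHA_CM_PER_MEV_P * float(energy_mev) ** P_EXPONENT


def energy_from_range(range_mm: float) -> float:
    """Inverse of `range_from_energy` (mm -> MeV)."""
    return float((range_mm / 10.0 / ALPHA_CM_PER_MEV_P) ** (1.0 / P_EXPONENT))


def straggling_sigma_mm(range_mm: float) -> float:
    """Range-straggling sigma in mm for a beam of water range ``range_mm``."""
    return 10.0 * STRAGGLING_COEF * (range_mm / 10.0) ** STRAGGLING_EXP


def _check_energy(energy_mev: float) -> None:
    lo, hi = ENERGY_BAND_MEV
    if not lo <= energy_mev <= hi:
        raise ValueError(f"energy {energy_mev} MeV outside modeled band {ENERGY_BAND_MEV}")


def bragg_curve(energy_mev: float, wepl_mm) -> np.ndarray:
    """Relative depth dose of a monoenergetic beam on a WEPL grid.

    The pristine curve is the stopping power of the range-energy relation,
    dE/dz proportional to (R0 - z)^(1/p - 1), numerically convolved with a
    Gaussian of width sigma(R0) for range straggling; the peak is
    normalized to 1 and the dose is exactly zero beyond R0 + 3 sigma.
    """
    _check_energy(energy_mev)
    wepl = np.asarray(wepl_mm, dtype=float)
    r0 = range_from_energy(energy_mev)
    sigma = straggling_sigma_mm(r0)
    h = min(0.1, sigma / 5.0)
    z = np.arange(-4.0 * sigma, r0 + 4.0 * sigma, h) + h / 2.0  # midpoints
    d0 = np.where(z < r0, np.power(np.clip(r0 - z, 1e-12, None), 1.0 / P_EXPONENT - 1.0), 0.0)
    kz = np.arange(-4.0 * sigma, 4.0 * sigma + h, h)
    kernel = np.exp(-0.5 * (kz / sigma) ** 2)
    kernel /= kernel.sum()
    d = np.convolve(d0, kernel, mode="same")
    d[z > r0 + 3.0 * sigma] = 0.0
    d /= d.max()
    out = np.interp(wepl, z, d, left=float(d[np.searchsorted(z, 0.0)]), right=0.0)
    out = np.where(wepl > r0 + 3.0 * sigma, 0.0, out)
    return out if out.ndim else float(out)


def sobp_weights(
    target_wepl_interval: tuple[float, float],
    energies: Sequence[float],
    flatness_tol: float = 0.03,
    grid_step_mm: float = 0.5,
) -> np.ndarray:
    """Nonnegative energy weights flattening the summed dose over a target.

    Energies whose range exceeds the distal edge + 3 sigma get weight zero
    (their dose cannot contribute without overshooting).  Raises when the
    available ranges cannot cover the interval; warns when the achieved
    flatness over the interval exceeds ``flatness_tol`` of its mean.
    """
    prox, dist = map(float, target_wepl_interval)
    if dist < prox:
        raise ValueError("target interval must have prox <= dist")
    energies = np.asarray(sorted(float(e) for e in energies))
    ranges = np.array([range_from_energy(e) for e in energies])
    sigmas = np.array([straggling_sigma_mm(r) for r in ranges])
    usable = ranges <= dist + 3.0 * sigmas
    if not np.any(usable):
        raise ValueError(
            f"no usable energy: all ranges {ranges.min():.1f}-{ranges.max():.1f} mm "
            f"overshoot distal edge {dist:.1f} mm + 3 sigma"
        )
    if ranges[usable].max() < dist - sigmas[usable].max():
        raise ValueError(
            f"interval not coverable: deepest usable range "
            f"{ranges[usable].max():.1f} mm < distal edge {dist:.1f} mm"
        )
    grid = np.arange(max(0.0, prox - 30.0), dist + 20.0 + grid_step_mm, grid_step_mm)
    curves = np.column_stack([bragg_curve(e, grid) for e in energies[usable]])
    mask = (grid >= prox) & (grid <= dist)
    if not np.any(mask):  # degenerate interval between grid samples
        mask = np.zeros_like(grid, dtype=bool)
        mask[np.argmin(np.abs(grid - 0.5 * (prox + dist)))] = True
    w_usable, _ = nnls(curves[mask], np.ones(int(mask.sum())))
    weights = np.zeros(energies.size)
    weights[usable] = w_usable
    total = curves[mask] @ w_usable
    mean = total.mean()
    if mean <= 0 or np.abs(total / mean - 1.0).max() > flatness_tol:
        warnings.warn(
            f"SOBP flatness {np.abs(total / max(mean, 1e-12) - 1.0).max():.3f} "
            f"exceeds {flatness_tol}; consider finer energy spacing",
            RuntimeWarning,
        )
    return weights


def sobp_dose(wepl_mm, energies: Sequence[float], weights: Sequence[float]) -> np.ndarray:
    """Weighted sum of Bragg curves on an arbitrary WEPL array."""
    wepl = np.asarray(wepl_mm, dtype=float)
    out = np.zeros_like(wepl)
    for e, w in zip(energies, weights):
        if w > 0:
            out += w * bragg_curve(e, wepl)
    return out


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PTVSphere:
    """Spherical planning target volume (mm, world coordinates)."""

    center: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class BeamSpec:
    """One parallel proton field.

    Gantry rotates in the axial (x, y) plane about the z axis; the couch is
    fixed at 0 degrees.  Gantry 0 points the beam along +y; positive angles
    rotate toward +x.  ``energies``/``weights`` are filled by `plan_beam`.
    """

    gantry_angle_deg: float
    isocenter: tuple[float, float, float]
    couch_angle_deg: float = 0.0
    energies: tuple[float, ...] = ()
    weights: tuple[float, ...] = ()
    prescription_gy: float = 60.0
    fractions: int = 30
    rbe: float = 1.1

    def __post_init__(self) -> None:
        if not -180.0 <= self.gantry_angle_deg < 180.0:
            raise ValueError("gantry angle must lie in [-180, 180)")
        if self.couch_angle_deg != 0.0:
            raise ValueError("only couch angle 0 is modeled")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")

    @property
    def direction(self) -> np.ndarray:
        th = math.radians(self.gantry_angle_deg)
        return np.array([math.sin(th), math.cos(th), 0.0])


@dataclass
class DepthDoseProfile:
    """Dose versus geometric depth along one ray."""

    depth_mm: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.dose < 0):
            raise ValueError("dose must be nonnegative")


@dataclass
class DoseGrid:
    """Per-voxel dose on the SPR map's grid (Gy; RBE-weighted when flagged)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    rbe_weighted: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose grid must be finite and nonnegative")


def wepl_along_ray(
    spr: SPRMap,
    origin_mm: Sequence[float],
    direction: Sequence[float],
    geometric_depths_mm: Sequence[float],
) -> np.ndarray | None:
    """Cumulative WEPL at given depths along a ray (Siddon traversal).

    WEPL(d) = integral of SPR over the ray from the ray origin to depth d,
    with SPR = 0 outside the grid; the result is monotone nondecreasing.
    Returns None when the ray misses the grid entirely.
    """
    o = np.asarray(origin_mm, dtype=float)
    u = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(u)
    if not math.isclose(norm, 1.0, rel_tol=1e-6):
        raise ValueError("direction must be a unit vector")
    u = u / norm
    depths = np.asarray(geometric_depths_mm, dtype=float)
    spacing = np.asarray(spr.spacing, dtype=float)
    grid_o = np.asarray(spr.origin, dtype=float)
    shape = np.asarray(spr.values.shape)
    lo = grid_o - spacing / 2.0
    hi = grid_o + (shape - 0.5) * spacing

    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        if abs(u[ax]) < 1e-12:
            if not lo[ax] <= o[ax] <= hi[ax]:
                return None
        else:
            ta = (lo[ax] - o[ax]) / u[ax]
            tb = (hi[ax] - o[ax]) / u[ax]
            t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
    if t1 <= max(t0, 0.0):
        return None
    t0 = max(t0, 0.0)

    knots = [np.array([t0, t1])]
    for ax in range(3):
        if abs(u[ax]) < 1e-12:
            continue
        planes = lo[ax] + spacing[ax] * np.arange(1, shape[ax])
        t = (planes - o[ax]) / u[ax]
        knots.append(t[(t > t0) & (t < t1)])
    t_knots = np.unique(np.concatenate(knots))
    mids = 0.5 * (t_knots[:-1] + t_knots[1:])
    pts = o[None, :] + mids[:, None] * u[None, :]
    idx = np.clip(np.round((pts - grid_o) / spacing).astype(int), 0, shape - 1)
    seg_spr = spr.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    seg_len = np.diff(t_knots)
    cum = np.concatenate([[0.0], np.cumsum(seg_spr * seg_len)])
    return np.interp(depths, t_knots, cum, left=0.0, right=float(cum[-1]))


def _affine_params(theta_rad: float, spacing, origin, iso):
    """Index-space matrix/offset for ndimage.affine_transform of a rotation
    about the isocenter in the axial plane."""
    c, s = math.cos(theta_rad), math.sin(theta_rad)
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    # snap numerical noise at multiples of 90 degrees so that exact flips map
    # voxel centers onto voxel centers (scipy treats -1e-16 as out of grid)
    rot[np.abs(rot) < 1e-12] = 0.0
    sp = np.asarray(spacing, dtype=float)
    og = np.asarray(origin, dtype=float)
    iso = np.asarray(iso, dtype=float)
    mat = rot * sp[None, :] / sp[:, None]
    off = (rot @ (og - iso) + iso - og) / sp
    return mat, off


def _resample_to_beam_frame(vol, theta_rad, spacing, origin, iso, cval=0.0):
    mat, off = _affine_params(theta_rad, spacing, origin, iso)
    return ndimage.affine_transform(vol, mat, offset=off, order=1,
                                    mode="constant", cval=cval)


def _resample_from_beam_frame(vol, theta_rad, spacing, origin, iso):
    mat, off = _affine_params(-theta_rad, spacing, origin, iso)
    return ndimage.affine_transform(vol, mat, offset=off, order=1,
                                    mode="constant", cval=0.0)


def plan_beam(
    spr: SPRMap,
    beam: BeamSpec,
    ptv: PTVSphere,
    energy_step_mev: float = 2.0,
) -> BeamSpec:
    """Choose SOBP energies and weights so the beam covers the PTV.

    The target WEPL interval is read on the central axis of the beam
    through the PTV sphere; energies are laid out in ``energy_step_mev``
    steps spanning it.  Returns a new BeamSpec with energies and weights
    filled in; reuse that spec on a second SPR map to compare dose under
    identical settings.
    """
    prox_w, dist_w = _ptv_wepl_interval(spr, beam, ptv)
    # peaks are stacked from the proximal to the distal interval edge; an
    # energy with range short of the proximal edge would let the weight fit
    # build an uncontrolled spike outside the flattened region
    e_lo = max(ENERGY_BAND_MEV[0], energy_from_range(max(prox_w, 10.0)))
    e_hi = min(ENERGY_BAND_MEV[1], energy_from_range(dist_w) + energy_step_mev)
    energies = np.arange(e_lo, e_hi + energy_step_mev / 2.0, energy_step_mev)
    if energies.size < 2:
        energies = np.array([e_lo, e_lo + energy_step_mev])
    weights = sobp_weights((prox_w, dist_w), energies)
    return replace(beam, energies=tuple(energies), weights=tuple(weights))


def _entry_point(spr: SPRMap, beam: BeamSpec) -> np.ndarray:
    extent = np.asarray(spr.values.shape) * np.asarray(spr.spacing)
    back = float(np.linalg.norm(extent)) + 1.0
    return np.asarray(beam.isocenter, dtype=float) - back * beam.direction


def _ptv_wepl_interval(spr: SPRMap, beam: BeamSpec, ptv: PTVSphere):
    start = _entry_point(spr, beam)
    iso_depth = float(np.linalg.norm(np.asarray(beam.isocenter) - start))
    depths = np.array([iso_depth - ptv.radius, iso_depth + ptv.radius])
    wepl = wepl_along_ray(spr, start, beam.direction, depths)
    if wepl is None:
        raise ValueError("beam central axis misses the SPR grid")
    return float(wepl[0]), float(wepl[1])


def compute_dose(
    spr: SPRMap,
    beams: Sequence[BeamSpec],
    ptv: PTVSphere,
    sigma_lat_mm: float = 5.0,
    field_margin_mm: float = 5.0,
    normalize: bool = True,
) -> DoseGrid:
    """Sum parallel-beam SOBP dose over all fields on the SPR map's grid.

    Per beam the SPR volume is resampled into the beam frame, WEPL is
    accumulated along the beam axis, the SOBP curve is evaluated per ray,
    a lateral aperture (PTV radius + margin, Gaussian penumbra) is applied,
    and the dose is resampled back.  When ``normalize`` is set, the summed
    dose is scaled so the PTV-mean RBE-weighted dose equals the
    prescription of the first beam.
    """
    if not beams:
        raise ValueError("need at least one beam")
    spacing = np.asarray(spr.spacing, dtype=float)
    origin = np.asarray(spr.origin, dtype=float)
    shape = spr.values.shape
    total = np.zeros(shape)
    for beam in beams:
        if not beam.energies:
            raise ValueError("beam has no energies; run plan_beam first")
        theta = math.radians(beam.gantry_angle_deg)
        iso = np.asarray(beam.isocenter, dtype=float)
        spr_bf = _resample_to_beam_frame(spr.values, theta, spacing, origin, iso)
        wepl = (np.cumsum(spr_bf, axis=1) - 0.5 * spr_bf) * spacing[1]
        # WEPL is measured from the grid edge; shift so that the planned
        # interval (measured from far outside) lines up: both differ only
        # by the SPR integral outside the grid, which is zero.
        dose_bf = sobp_dose(wepl, beam.energies, beam.weights)
        ax_x = (origin[0] + spacing[0] * np.arange(shape[0])) - iso[0]
        ax_z = (origin[2] + spacing[2] * np.arange(shape[2])) - iso[2]
        r2 = ax_x[:, None] ** 2 + ax_z[None, :] ** 2
        aperture = (r2 <= (ptv.radius + field_margin_mm) ** 2).astype(float)
        if sigma_lat_mm > 0:
            aperture = ndimage.gaussian_filter(
                aperture, sigma=(sigma_lat_mm / spacing[0], sigma_lat_mm / spacing[2])
            )
        dose_bf *= aperture[:, None, :]
        total += _resample_from_beam_frame(dose_bf, theta, spacing, origin, iso)
    total = np.clip(total, 0.0, None)
    rbe = beams[0].rbe
    if normalize:
        mask = _sphere_mask(shape, spacing, origin, ptv)
        mean = total[mask].mean() if mask.any() else 0.0
        if mean <= 0:
            raise ValueError("no dose delivered to the PTV; check beam setup")
        total *= beams[0].prescription_gy / (rbe * mean)
    return DoseGrid(values=total * rbe, spacing=tuple(spr.spacing),
                    origin=tuple(spr.origin), rbe_weighted=True)


def _sphere_mask(shape, spacing, origin, ptv: PTVSphere) -> np.ndarray:
    axes = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    cx, cy, cz = ptv.center
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= ptv.radius**2


def _grid_entry_depth(spr: SPRMap, origin_mm, direction) -> float | None:
    """Depth along the ray at which it first enters the grid bounding box."""
    o = np.asarray(origin_mm, dtype=float)
    u = np.asarray(direction, dtype=float)
    spacing = np.asarray(spr.spacing, dtype=float)
    grid_o = np.asarray(spr.origin, dtype=float)
    shape = np.asarray(spr.values.shape)
    lo = grid_o - spacing / 2.0
    hi = grid_o + (shape - 0.5) * spacing
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        if abs(u[ax]) < 1e-12:
            if not lo[ax] <= o[ax] <= hi[ax]:
                return None
        else:
            ta = (lo[ax] - o[ax]) / u[ax]
            tb = (hi[ax] - o[ax]) / u[ax]
            t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
    return None if t1 <= max(t0, 0.0) else max(t0, 0.0)


def central_axis_profile(
    spr: SPRMap, beam: BeamSpec, depth_step_mm: float = 0.5
) -> DepthDoseProfile:
    """SOBP depth-dose along the beam's central axis through this SPR map.

    Depth 0 is where the central axis enters the image grid, so reported
    ranges are measured from the phantom-side grid face.
    """
    if not beam.energies:
        raise ValueError("beam has no energies; run plan_beam first")
    start = _entry_point(spr, beam)
    t_entry = _grid_entry_depth(spr, start, beam.direction)
    if t_entry is None:
        raise ValueError("beam central axis misses the SPR grid")
    start = start + t_entry * beam.direction
    extent = float(np.linalg.norm(np.asarray(spr.values.shape) * np.asarray(spr.spacing)))
    depths = np.arange(0.0, extent + 2.0, depth_step_mm)
    wepl = wepl_along_ray(spr, start, beam.direction, depths)
    dose = sobp_dose(wepl, beam.energies, beam.weights)
    return DepthDoseProfile(depth_mm=depths, dose=dose)


def r90_range(profile: DepthDoseProfile) -> float:
    """Distal depth (mm) where dose first falls to 90% of the maximum.

    Scans distally from the global maximum and interpolates linearly
    between the bracketing samples.  Raises when the grid is truncated
    before the falloff.
    """
    dose = np.asarray(profile.dose, dtype=float)
    depth = np.asarray(profile.depth_mm, dtype=float)
    imax = int(np.argmax(dose))
    level = 0.9 * dose[imax]
    below = np.nonzero(dose[imax:] < level)[0]
    if below.size == 0:
        raise ValueError("no distal falloff below 90% on the profile grid")
    j = imax + int(below[0])
    d0, d1 = dose[j - 1], dose[j]
    z0, z1 = depth[j - 1], depth[j]
    return float(z0 + (d0 - level) / (d0 - d1) * (z1 - z0))


def range_comparison(
    ranges_spectral: Sequence[float],
    ranges_sect: Sequence[float],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tabulate spectral-vs-SECT R90 ranges per beam.

    difference = spectral - sect (mm); deviation = 100 * difference / sect.
    Both are reported rounded half-away-from-zero to 2 decimals.
    """
    rs = np.asarray(ranges_spectral, dtype=float)
    rc = np.asarray(ranges_sect, dtype=float)
    if rs.shape != rc.shape:
        raise ValueError("beam lists must match")
    labels = list(labels) if labels is not None else [f"beam_{i}" for i in range(rs.size)]
    rows = []
    for lab, a, b in zip(labels, rs, rc):
        diff = a - b
        rows.append({
            "beam": lab,
            "range_spectral_mm": a,
            "range_sect_mm": b,
            "deviation_pct": round_half_away(100.0 * diff / b, 2),
            "difference_mm": round_half_away(diff, 2),
        })
    return pd.DataFrame(rows)
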