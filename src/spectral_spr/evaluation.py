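"""Dose-comparison metrics: relative dose difference and the 3D gamma index.

Gamma uses global normalization (dose criterion as a percentage of the
reference maximum) with a low-dose cutoff, and an exact exhaustive search
over all voxel offsets within three times the distance-to-agreement
radius; grids are desk-scale so no approximation is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .proton_dose import DoseGrid

__all__ = [
    "GammaResult",
    "DoseDifferenceResult",
    "relative_dose_difference",
    "gamma_index",
]


def _check_matched(ref: DoseGrid, other: DoseGrid) -> None:
    if ref.values.shape != other.values.shape or ref.spacing != other.spacing:
        raise ValueError("dose grids are not on a common voxel grid")


@dataclass
class DoseDifferenceResult:
    """Voxelwise percent difference 100*(eval-ref)/ref above a cutoff."""

    percent: np.ndarray  # NaN outside the evaluated mask
    mask: np.ndarray
    cutoff_fraction: float

    def extreme_in(self, region_mask: np.ndarray) -> float:
        """Signed difference of largest magnitude within a region."""
        vals = self.percent[region_mask & self.mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan")
        return float(vals[np.argmax(np.abs(vals))])


def relative_dose_difference(
    ref: DoseGrid, eval_grid: DoseGrid, cutoff_fraction: float = 0.1
) -> DoseDifferenceResult:
    """Percent dose difference where the reference exceeds the cutoff.

    The cutoff is a fraction of the reference maximum; voxels below it are
    excluded (NaN) since the ratio is unstable at near-zero dose.
    """
    _check_matched(ref, eval_grid)
    cutoff = cutoff_fraction * ref.values.max()
    mask = ref.values > cutoff
    percent = np.full(ref.values.shape, np.nan)
    percent[mask] = 100.0 * (eval_grid.values[mask] - ref.values[mask]) / ref.values[mask]
    return DoseDifferenceResult(percent=percent, mask=mask, cutoff_fraction=cutoff_fraction)


@dataclass
class GammaResult:
    criterion: tuple[float, float]  # (dose %, DTA mm)
    pass_rate: float
    gamma_volume: np.ndarray  # NaN outside the evaluated mask
    evaluated_mask: np.ndarray


def gamma_index(
    ref: DoseGrid,
    eval_grid: DoseGrid,
    dose_pct: float = 2.0,
    dta_mm: float = 2.0,
    cutoff_pct: float = 10.0,
) -> GammaResult:
    """Global 3D gamma of ``eval_grid`` against ``ref``.

    For each reference voxel above the low-dose cutoff,

        gamma = min over eval voxels within 3*dta of
                sqrt((dDose/dD)^2 + (dist/dta)^2),

    with dD = dose_pct% of the global reference maximum.  A voxel passes
    when gamma <= 1; the pass rate is the passing fraction of the
    evaluated mask, in percent.
    """
    _check_matched(ref, eval_grid)
    ref_v = ref.values
    ev_v = eval_grid.values
    dd = dose_pct / 100.0 * ref_v.max()
    if dd <= 0:
        raise ValueError("reference dose is identically zero")
    mask = ref_v >= cutoff_pct / 100.0 * ref_v.max()
    if not mask.any():
        raise ValueError("all voxels below the low-dose cutoff")
    spacing = np.asarray(ref.spacing, dtype=float)
    radius = 3.0 * dta_mm
    nmax = np.floor(radius / spacing).astype(int)
    g2 = np.full(ref_v.shape, np.inf)
    for off in product(*(range(-n, n + 1) for n in nmax)):
        dist2 = float(np.sum((np.asarray(off) * spacing) ** 2))
        if dist2 > radius**2:
            continue
        src = tuple(
            slice(max(o, 0), ref_v.shape[i] + min(o, 0)) for i, o in enumerate(off)
        )
        dst = tuple(
            slice(max(-o, 0), ref_v.shape[i] + min(-o, 0)) for i, o in enumerate(off)
        )
        cand = ((ev_v[src] - ref_v[dst]) / dd) ** 2 + dist2 / dta_mm**2
        np.minimum(g2[dst], cand, out=g2[dst])
    gamma = np.sqrt(g2)
    gamma_masked = np.where(mask, gamma, np.nan)
    pass_rate = 100.0 * float((gamma[mask] <= 1.0).sum()) / float(mask.sum())
    return GammaResult(criterion=(dose_pct, dta_mm), pass_rate=pass_rate,
                       gamma_volume=gamma_masked, evaluated_mask=mask)
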