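"""Energy-pair RED calibration, RED->SPR polyline and optimal-pair search.

The spectral route estimates relative electron density (RED) from a pair of
virtual-monoenergetic CT numbers,

    RED = c_e * (HU1/1000 + 1) + (1 - c_e) * (HU2/1000 + 1),

with one scalar weight c_e fitted per energy pair against the reference
REDs of the tissue library (a closed-form least-squares problem).  RED is
converted to stopping-power ratio through a four-branch polyline in
SPR/RED, and for each tissue the pair minimizing the absolute percent SPR
residual over all C(15, 2) = 105 pairs of the 70-140 keV / 5 keV grid is
recorded in a lookup table.  A group-wise piecewise-linear HU->SPR curve
serves as the single-energy-CT (SECT) stoichiometric baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .tissue_library import TissueSurrogate

__all__ = [
    "SingularFitError",
    "red_from_pair",
    "fit_ce",
    "polyline_spr_over_red",
    "spr_from_red",
    "percent_deviation",
    "round_half_away",
    "EnergyPairModel",
    "EnergyPairRegressor",
    "evaluate_pair",
    "evaluate_all_pairs",
    "OptimalPairLUT",
    "LUTEntry",
    "find_optimal_pairs",
    "residual_surface",
    "group_rmse",
    "SECTCalibration",
    "SECTCalibrator",
    "sect_calibrate",
    "sect_convert",
]


class SingularFitError(ValueError):
    """The two HU channels are identical; c_e is not identifiable."""


# ---------------------------------------------------------------------------
# Scalar building blocks
# ---------------------------------------------------------------------------

def red_from_pair(hu1, hu2, c_e):
    """RED from a VM HU pair and the fitted mixing weight c_e."""
    hu1 = np.asarray(hu1, dtype=float)
    hu2 = np.asarray(hu2, dtype=float)
    return c_e * (hu1 / 1000.0 + 1.0) + (1.0 - c_e) * (hu2 / 1000.0 + 1.0)


def fit_ce(hu1s, hu2s, reference_reds) -> float:
    """Closed-form least-squares c_e over a set of tissues.

    Minimizes sum((red_from_pair - reference_red)^2) in the single scalar.
    Raises `SingularFitError` when the two channels coincide element-wise.
    """
    x1 = np.asarray(hu1s, dtype=float) / 1000.0 + 1.0
    x2 = np.asarray(hu2s, dtype=float) / 1000.0 + 1.0
    red = np.asarray(reference_reds, dtype=float)
    if x1.shape != x2.shape or x1.shape != red.shape:
        raise ValueError("hu1s, hu2s and reference_reds must have equal length")
    if x1.size < 2:
        raise ValueError("need at least 2 tissues to fit c_e")
    d = x1 - x2
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise SingularFitError("HU channels identical for every tissue")
    return float(np.dot(d, red - x2) / denom)


_POLYLINE_BREAKS = (0.9, 1.035, 1.4, 2.0)


def polyline_spr_over_red(red):
    """Four-branch SPR/RED conversion ratio as a function of RED.

    Branches: ratio = 1 below RED 0.9; two descending segments through
    (0.9, 1.028) and (1.035, 1.0); a final segment through (1.4, 0.973) up
    to RED 2.0.  The curve is intentionally discontinuous at 0.9 (the value
    at 0.9 is 1.028).  RED outside (0, 2.0] is clamped to the nearest
    branch end with a warning, since noisy voxels can exceed the insert
    range.
    """
    red = np.asarray(red, dtype=float)
    scalar = red.ndim == 0
    red = np.atleast_1d(red)
    if np.any(red <= 0.0) or np.any(red > 2.0):
        warnings.warn("RED outside (0, 2.0]; clamped to branch ends", RuntimeWarning,
                      stacklevel=2)
        red = np.clip(red, np.finfo(float).tiny, 2.0)
    ratio = np.select(
        [red < 0.9, red < 1.035, red < 1.4],
        [1.0,
         -0.2074 * (red - 0.9) + 1.028,
         -0.074 * (red - 1.035) + 1.0],
        default=-0.0517 * (red - 1.4) + 0.973,
    )
    return float(ratio[0]) if scalar else ratio


def spr_from_red(red):
    """SPR = RED * polyline ratio."""
    red_c = np.clip(np.asarray(red, dtype=float), np.finfo(float).tiny, 2.0)
    out = red_c * polyline_spr_over_red(red)
    return float(out) if np.ndim(red) == 0 else out


def percent_deviation(predicted, reference):
    """100 * (predicted - reference) / reference."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    out = 100.0 * (predicted - reference) / reference
    return float(out) if out.ndim == 0 else out


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (reporting convention for deviations)."""
    q = Decimal(10) ** -ndigits
    d = Decimal(repr(float(value)))
    return float(d.copy_abs().quantize(q, rounding=ROUND_HALF_UP).copy_sign(d))


# ---------------------------------------------------------------------------
# Per-pair model and the sklearn-style estimator behind it
# ---------------------------------------------------------------------------

class EnergyPairRegressor(BaseEstimator, RegressorMixin):
    """Predict RED (and SPR) from one VM energy pair.

    A scikit-learn style estimator: ``fit(X, y)`` takes ``X`` of shape
    (n_tissues, 2) holding the HU values at the two energies and ``y`` the
    reference REDs, and solves the closed-form least squares for the single
    mixing weight, stored as ``c_e_``.

    Parameters
    ----------
    e1, e2 : float or None
        The pair's energies in keV (metadata; e1 < e2 when given).
    """

    def __init__(self, e1: float | None = None, e2: float | None = None):
        self.e1 = e1
        self.e2 = e2

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_tissues, 2)")
        if self.e1 is not None and self.e2 is not None and not self.e1 < self.e2:
            raise ValueError("require e1 < e2")
        self.c_e_ = fit_ce(X[:, 0], X[:, 1], y)
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "c_e_"):
            raise AttributeError("EnergyPairRegressor is not fitted")
        return red_from_pair(X[:, 0], X[:, 1], self.c_e_)

    def predict_spr(self, X):
        return spr_from_red(self.predict(X))


@dataclass
class EnergyPairModel:
    """A fitted (E1, E2) pair with per-tissue predictions and residuals."""

    e1: float
    e2: float
    c_e: float
    per_tissue_predicted_red: dict[str, float]
    per_tissue_predicted_spr: dict[str, float]
    per_tissue_residual_pct: dict[str, float]

    @property
    def pair(self) -> tuple[float, float]:
        return (self.e1, self.e2)


def evaluate_pair(
    pair: tuple[float, float],
    hu1s: Sequence[float],
    hu2s: Sequence[float],
    tissues: Sequence[TissueSurrogate],
) -> EnergyPairModel:
    """Fit c_e for one pair and report per-tissue SPR residuals (percent)."""
    e1, e2 = float(pair[0]), float(pair[1])
    reds = [t.reference_red for t in tissues]
    reg = EnergyPairRegressor(e1, e2).fit(np.column_stack([hu1s, hu2s]), reds)
    pred_red = reg.predict(np.column_stack([hu1s, hu2s]))
    pred_spr = spr_from_red(pred_red)
    residual = {
        t.name: percent_deviation(s, t.reference_spr)
        for t, s in zip(tissues, pred_spr)
    }
    return EnergyPairModel(
        e1=e1, e2=e2, c_e=reg.c_e_,
        per_tissue_predicted_red=dict(zip((t.name for t in tissues), pred_red)),
        per_tissue_predicted_spr=dict(zip((t.name for t in tissues), pred_spr)),
        per_tissue_residual_pct=residual,
    )


def evaluate_all_pairs(
    vm_means: pd.DataFrame, tissues: Sequence[TissueSurrogate]
) -> dict[tuple[float, float], EnergyPairModel]:
    """Evaluate every unordered energy pair of the VM mean-HU table.

    ``vm_means`` is indexed by tissue name with one column per VM energy
    (as produced by `vm_forward_model.vm_means_table`).  Degenerate pairs
    (identical HU in both channels) are skipped with a warning.
    """
    energies = sorted(float(c) for c in vm_means.columns)
    names = [t.name for t in tissues]
    table = vm_means.loc[names]
    models: dict[tuple[float, float], EnergyPairModel] = {}
    for e1, e2 in combinations(energies, 2):
        try:
            models[(e1, e2)] = evaluate_pair(
                (e1, e2), table[e1].to_numpy(), table[e2].to_numpy(), tissues
            )
        except SingularFitError:
            warnings.warn(f"pair {(e1, e2)} degenerate; skipped", RuntimeWarning)
    return models


# ---------------------------------------------------------------------------
# Optimal-pair lookup table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LUTEntry:
    e1: float
    e2: float
    c_e: float
    residual_pct: float
    mean_hu_anchor: float


@dataclass
class OptimalPairLUT:
    """tissue -> (optimal pair, fitted c_e, minimal residual, HU anchor)."""

    entries: dict[str, LUTEntry] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tissue": name, "e1_kev": e.e1, "e2_kev": e.e2, "c_e": e.c_e,
             "residual_pct": e.residual_pct, "mean_hu_anchor": e.mean_hu_anchor}
            for name, e in self.entries.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OptimalPairLUT":
        df = pd.read_csv(path)
        entries = {
            str(r.tissue): LUTEntry(float(r.e1_kev), float(r.e2_kev), float(r.c_e),
                                    float(r.residual_pct), float(r.mean_hu_anchor))
            for r in df.itertuples()
        }
        return cls(entries=entries)


def find_optimal_pairs(
    models: Mapping[tuple[float, float], EnergyPairModel],
    tissues: Sequence[TissueSurrogate],
    anchors: Mapping[str, float],
) -> OptimalPairLUT:
    """Select, per tissue, the pair minimizing |percent SPR residual|.

    Ties are broken lexicographically on (e1, e2).  ``anchors`` carries the
    per-tissue mean CT number used later by region matching.
    """
    if not models:
        raise ValueError("no valid energy-pair models")
    lut = OptimalPairLUT()
    ordered = sorted(models.keys())
    for t in tissues:
        best = None
        for pair in ordered:
            m = models[pair]
            r = m.per_tissue_residual_pct[t.name]
            if best is None or abs(r) < abs(best[1]):
                best = (pair, r, m.c_e)
        pair, r, c_e = best
        lut.entries[t.name] = LUTEntry(
            e1=pair[0], e2=pair[1], c_e=c_e, residual_pct=r,
            mean_hu_anchor=float(anchors[t.name]),
        )
    return lut


def residual_surface(
    models: Mapping[tuple[float, float], EnergyPairModel]
) -> pd.DataFrame:
    """Long-format (tissue, e1, e2, residual_pct) table for surface plots."""
    rows = []
    for (e1, e2), m in sorted(models.items()):
        for name, r in m.per_tissue_residual_pct.items():
            rows.append({"tissue": name, "e1": e1, "e2": e2, "residual_pct": r})
    return pd.DataFrame(rows)


def group_rmse(
    residuals_pct: Mapping[str, float], grouping: Mapping[str, str]
) -> dict[str, float]:
    """Root-mean-square percent residual per tissue group."""
    groups: dict[str, list[float]] = {}
    for name, r in residuals_pct.items():
        if name not in grouping:
            raise KeyError(f"tissue {name!r} has no group assignment")
        groups.setdefault(grouping[name], []).append(float(r))
    out = {}
    for g, vals in groups.items():
        if not vals:
            warnings.warn(f"group {g!r} empty; excluded", RuntimeWarning)
            continue
        out[g] = float(np.sqrt(np.mean(np.square(vals))))
    return out


# ---------------------------------------------------------------------------
# SECT stoichiometric baseline
# ---------------------------------------------------------------------------

_GROUP_ORDER = ("lung", "soft", "bone")


@dataclass
class SECTCalibration:
    """Piecewise-linear HU -> SPR conversion (ordered breakpoint nodes)."""

    nodes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        hu = [n[0] for n in self.nodes]
        if any(b <= a for a, b in zip(hu, hu[1:])):
            raise ValueError("node HU values must be strictly increasing")
        if any(n[1] < 0 for n in self.nodes):
            raise ValueError("node SPR values must be nonnegative")


class SECTCalibrator(BaseEstimator, RegressorMixin):
    """Group-wise piecewise-linear HU->SPR baseline calibration.

    ``fit(X, y, groups=...)`` fits one least-squares line per tissue group
    (lung, soft, bone) over that group's HU span and joins consecutive
    segments with connecting segments, yielding a continuous piecewise-
    linear curve stored as ``nodes_``.  ``predict`` interpolates and
    extrapolates flat beyond the end nodes.  This is a documented stand-in
    for a scanner-specific stoichiometric calibration.
    """

    def fit(self, X, y, groups=None):
        hu = np.asarray(X, dtype=float).reshape(-1)
        spr = np.asarray(y, dtype=float).reshape(-1)
        if groups is None:
            raise ValueError("groups (per-tissue group labels) are required")
        groups = np.asarray(groups, dtype=object)
        present = [g for g in _GROUP_ORDER if np.any(groups == g)]
        if len(hu) < 3 or len(present) < 2:
            raise ValueError("need >=3 tissues spanning at least two groups")
        segments = []
        for g in present:
            m = groups == g
            h, s = hu[m], spr[m]
            if h.size == 1:
                a, b = 0.0, float(s[0])
            else:
                a, b = np.polyfit(h, s, 1)
            segments.append((float(h.min()), float(h.max()), float(a), float(b)))
        segments.sort(key=lambda seg: seg[0])
        for (lo1, hi1, *_), (lo2, *_rest) in zip(segments, segments[1:]):
            if lo2 <= hi1:
                raise ValueError("group HU spans overlap; non-monotone ordering")
        nodes: list[tuple[float, float]] = []
        for lo, hi, a, b in segments:
            nodes.append((lo, max(a * lo + b, 0.0)))
            if hi > lo:
                nodes.append((hi, max(a * hi + b, 0.0)))
        self.nodes_ = tuple(nodes)
        SECTCalibration(self.nodes_)  # validates
        return self

    def predict(self, X):
        if not hasattr(self, "nodes_"):
            raise AttributeError("SECTCalibrator is not fitted")
        hu = np.asarray(X, dtype=float)
        xs = np.array([n[0] for n in self.nodes_])
        ys = np.array([n[1] for n in self.nodes_])
        out = np.interp(hu, xs, ys)
        return float(out) if np.ndim(X) == 0 else out


def sect_calibrate(
    hu_120kvp: Sequence[float],
    reference_sprs: Sequence[float],
    groups: Sequence[str],
) -> SECTCalibration:
    """Fit the SECT baseline curve; see `SECTCalibrator`."""
    est = SECTCalibrator().fit(hu_120kvp, reference_sprs, groups=groups)
    return SECTCalibration(nodes=est.nodes_)


def sect_convert(cal: SECTCalibration, hu):
    """Convert HU to SPR with a fitted SECT calibration curve."""
    xs = np.array([n[0] for n in cal.nodes])
    ys = np.array([n[1] for n in cal.nodes])
    out = np.interp(np.asarray(hu, dtype=float), xs, ys)
    return float(out) if np.ndim(hu) == 0 else out
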