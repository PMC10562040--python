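"""Threshold segmentation and segmentation-based SPR map construction.

A CT volume is cut into regions by ordered HU thresholds; each region is
matched to a library tissue by closest mean CT number against the lookup
table's anchors; and each region's voxels are converted to stopping-power
ratio with that tissue's optimal energy pair (spectral route) or with the
piecewise-linear baseline curve (SECT route).  For any homogeneous region
the voxel path commutes with the scalar tissue-level pipeline by
construction: both apply the same pair, c_e and polyline to the same HU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .spectral_calibration import (
    OptimalPairLUT,
    SECTCalibration,
    red_from_pair,
    sect_convert,
    spr_from_red,
)
from .vm_forward_model import VMImageSet

__all__ = [
    "RegionInfo",
    "LabelMap",
    "SPRMap",
    "ThresholdSegmenter",
    "threshold_segment",
    "match_regions",
    "build_spr_map",
    "build_sect_spr_map",
    "remove_small_components",
]

#: Voxels below this HU are treated as air regardless of their label.
AIR_THRESHOLD_HU = -950.0
DEFAULT_AIR_SPR = 0.001


@dataclass(frozen=True)
class RegionInfo:
    mean_hu: float
    voxel_count: int
    empty: bool = False
    matched_tissue: str | None = None
    pair: tuple[float, float] | None = None
    c_e: float | None = None


@dataclass
class LabelMap:
    """Integer label per voxel plus per-label region metadata."""

    labels: np.ndarray
    metadata: dict[int, RegionInfo] = field(default_factory=dict)

    def populated_labels(self) -> list[int]:
        return [k for k, m in self.metadata.items() if not m.empty]


@dataclass
class SPRMap:
    """Voxelwise stopping-power-ratio volume with grid metadata."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SPR map contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("SPR map contains negative values")


class ThresholdSegmenter(BaseEstimator, TransformerMixin):
    """Stateless transformer cutting an HU volume at ordered thresholds.

    ``transform`` maps a voxel with HU in (t_k, t_{k+1}] to label k+1, so k
    thresholds produce k+1 label classes (1-based; 0 is never produced).
    """

    def __init__(self, thresholds: Sequence[float] = ()):
        self.thresholds = tuple(thresholds)

    def fit(self, X=None, y=None):
        t = self.thresholds
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        return self

    def transform(self, X) -> np.ndarray:
        self.fit()
        vol = np.asarray(X, dtype=float)
        return (np.digitize(vol, self.thresholds, right=True) + 1).astype(np.int32)


def threshold_segment(volume, thresholds: Sequence[float]) -> LabelMap:
    """Segment an HU volume into len(thresholds)+1 labeled regions."""
    labels = ThresholdSegmenter(thresholds).fit().transform(volume)
    vol = np.asarray(volume, dtype=float)
    metadata: dict[int, RegionInfo] = {}
    for k in range(1, len(tuple(thresholds)) + 2):
        mask = labels == k
        n = int(mask.sum())
        if n == 0:
            metadata[k] = RegionInfo(mean_hu=float("nan"), voxel_count=0, empty=True)
        else:
            metadata[k] = RegionInfo(mean_hu=float(vol[mask].mean()), voxel_count=n)
    return LabelMap(labels=labels, metadata=metadata)


def match_regions(label_map: LabelMap, lut: OptimalPairLUT) -> LabelMap:
    """Assign each populated region the LUT tissue with the closest anchor HU.

    Ties are broken toward the lower anchor value.
    """
    if not lut.entries:
        raise ValueError("empty lookup table")
    anchors = sorted(lut.entries.items(), key=lambda kv: kv[1].mean_hu_anchor)
    metadata = {}
    for k, info in label_map.metadata.items():
        if info.empty:
            metadata[k] = info
            continue
        best = min(anchors, key=lambda kv: (abs(info.mean_hu - kv[1].mean_hu_anchor),
                                            kv[1].mean_hu_anchor))
        name, entry = best
        metadata[k] = replace(info, matched_tissue=name,
                              pair=(entry.e1, entry.e2), c_e=entry.c_e)
    return LabelMap(labels=label_map.labels, metadata=metadata)


def build_spr_map(
    vm: VMImageSet,
    labels: LabelMap,
    lut: OptimalPairLUT,
    air_spr: float = DEFAULT_AIR_SPR,
    air_threshold_hu: float = AIR_THRESHOLD_HU,
) -> SPRMap:
    """Convert VM volumes to SPR region by region with each optimal pair.

    Every voxel of a matched region r gets RED from the pair assigned to r
    (with that pair's fitted c_e) and SPR through the polyline.  Unlabeled
    voxels, and voxels darker than ``air_threshold_hu`` in the region's
    lower-energy image, get ``air_spr``.
    """
    missing = sorted(
        {e for info in labels.metadata.values() if info.pair
         for e in info.pair if e not in vm.energies}
    )
    if missing:
        raise ValueError(f"assigned energies missing from VM set: {missing}")
    values = np.full(vm.shape, air_spr, dtype=float)
    regions = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # clamp warnings on noise
        for k, info in labels.metadata.items():
            if info.empty:
                continue
            if info.matched_tissue is None:
                raise ValueError(f"region {k} has no tissue assignment; "
                                 "run match_regions first")
            mask = labels.labels == k
            hu1 = vm.volume(info.pair[0])[mask]
            hu2 = vm.volume(info.pair[1])[mask]
            spr = spr_from_red(red_from_pair(hu1, hu2, info.c_e))
            spr = np.where(hu1 < air_threshold_hu, air_spr, spr)
            values[mask] = spr
            regions[str(k)] = {"tissue": info.matched_tissue,
                               "pair_kev": list(info.pair), "c_e": info.c_e}
    return SPRMap(values=values, spacing=vm.spacing, origin=vm.origin,
                  provenance={"method": "spectral", "regions": regions,
                              "air_spr": air_spr})


def build_sect_spr_map(
    volume_120kvp: np.ndarray,
    cal: SECTCalibration,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    air_spr: float = DEFAULT_AIR_SPR,
    air_threshold_hu: float = AIR_THRESHOLD_HU,
) -> SPRMap:
    """Voxelwise SECT baseline conversion of a 120 kVp volume."""
    vol = np.asarray(volume_120kvp, dtype=float)
    values = sect_convert(cal, vol)
    values = np.where(vol < air_threshold_hu, air_spr, values)
    return SPRMap(values=values, spacing=tuple(spacing), origin=tuple(origin),
                  provenance={"method": "sect", "n_nodes": len(cal.nodes),
                              "air_spr": air_spr})


def remove_small_components(label_map: LabelMap, min_voxels: int) -> LabelMap:
    """Optional cleanup: drop connected components smaller than ``min_voxels``.

    Small components are reassigned to label 0 (background).  Off by
    default in every pipeline path.
    """
    from scipy import ndimage

    labels = label_map.labels.copy()
    for k in label_map.populated_labels():
        comp, n = ndimage.label(labels == k)
        for c in range(1, n + 1):
            m = comp == c
            if m.sum() < min_voxels:
                labels[m] = 0
    out = LabelMap(labels=labels, metadata={})
    for k, info in label_map.metadata.items():
        n = int((labels == k).sum())
        out.metadata[k] = replace(info, voxel_count=n, empty=n == 0)
    return out
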