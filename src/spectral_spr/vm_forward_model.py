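"""Synthetic virtual-monoenergetic (VM) image generator.

This module stands in for the spectral scanner: it predicts the mean CT
number of a tissue surrogate at any VM energy from its elemental
composition, and rasterizes labeled 3D phantoms with additive Gaussian HU
noise.  The attenuation model is the classical photoelectric / coherent /
Compton decomposition on a per-electron basis,

    sigma(Z, E) = A_ph * Z^4.62 * E^-3  +  A_coh * Z^2.86 * E^-2  +  sigma_KN(E),

normalized to water so that a water voxel reads 0 HU at every energy.  The
two coefficients were fixed once, together with the three-point 120 kVp
spectrum weights, so that the simulated single-energy CT numbers of the
four anchor tissues (50% CaCO3, HE Blood 100, HE Blood 40, LN-300 lung)
match 881.44 / 106.44 / 45.61 / -702.66 HU; the solved constants are
committed below.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import ELEMENTS, WATER_COMPOSITION
from .tissue_library import TissueSurrogate

__all__ = [
    "DEFAULT_VM_ENERGIES",
    "VMImageSet",
    "PhantomSpec",
    "Region",
    "Ellipsoid",
    "Cylinder",
    "Box",
    "PhantomRealization",
    "attenuation_relative_to_water",
    "simulate_vm_hu",
    "simulate_sect_hu",
    "rasterize_phantom",
    "pediatric_phantom_spec",
    "vm_means_table",
    "write_phantom",
]

# --- committed forward-model constants (fixture build; see docs/methods.md) ---
A_PH = 0.411345317         # photoelectric coefficient, KN units
A_COH = 6.0e-4             # coherent coefficient, ~7% of water sigma at 70 keV
PE_EXPONENT = 4.62
COH_EXPONENT = 2.86
#: (energy keV, weight) three-point stand-in for the 120 kVp spectrum.
SECT_SPECTRUM = ((50.0, 0.33257284), (70.0, 0.38268047), (90.0, 0.28474669))
ENERGY_BAND_KEV = (40.0, 200.0)
AIR_HU = -1000.0

DEFAULT_VM_ENERGIES: tuple[float, ...] = tuple(float(e) for e in range(70, 141, 5))


def _klein_nishina(energy_kev):
    """Total Klein-Nishina cross-section per electron (units of 2*pi*r_e^2)."""
    k = np.asarray(energy_kev, dtype=float) / 511.0
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    return t1 + np.log1p(2 * k) / (2 * k) - (1 + 3 * k) / (1 + 2 * k) ** 2


def _per_electron_sigma(electron_fractions: Mapping[str, float], energy_kev):
    e = np.asarray(energy_kev, dtype=float)
    pe = sum(lam * ELEMENTS[el][0] ** PE_EXPONENT for el, lam in electron_fractions.items())
    coh = sum(lam * ELEMENTS[el][0] ** COH_EXPONENT for el, lam in electron_fractions.items())
    return A_PH * pe * e**-3.0 + A_COH * coh * e**-2.0 + _klein_nishina(e)


def _water_electron_fractions() -> dict[str, float]:
    num = {el: w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in WATER_COMPOSITION.items()}
    tot = sum(num.values())
    return {el: v / tot for el, v in num.items()}


def _check_band(energy_kev) -> None:
    e = np.asarray(energy_kev, dtype=float)
    lo, hi = ENERGY_BAND_KEV
    if np.any(e < lo) or np.any(e > hi):
        raise ValueError(f"energy {energy_kev} keV outside modeled band {ENERGY_BAND_KEV}")


def attenuation_relative_to_water(tissue: TissueSurrogate, energy_kev):
    """mu/mu_water of ``tissue`` at one or more VM energies (keV).

    Water returns exactly 1 at every energy by self-normalization.
    """
    _check_band(energy_kev)
    num = _per_electron_sigma(tissue.electron_fractions(), energy_kev)
    den = _per_electron_sigma(_water_electron_fractions(), energy_kev)
    return tissue.reference_red * num / den


def simulate_vm_hu(tissue: TissueSurrogate, energy_kev):
    """Noiseless VM CT number: HU = 1000 * (mu/mu_w - 1)."""
    return 1000.0 * (attenuation_relative_to_water(tissue, energy_kev) - 1.0)


def simulate_sect_hu(tissue: TissueSurrogate) -> float:
    """120 kVp-equivalent CT number: spectrum-weighted monoenergetic average."""
    energies = np.array([e for e, _ in SECT_SPECTRUM])
    weights = np.array([w for _, w in SECT_SPECTRUM])
    mu = attenuation_relative_to_water(tissue, energies)
    return float(1000.0 * (np.dot(weights, mu) - 1.0))


def vm_means_table(tissues: Sequence[TissueSurrogate], energies: Sequence[float] = DEFAULT_VM_ENERGIES):
    """Per-tissue noiseless mean HU at each VM energy, as a DataFrame."""
    import pandas as pd

    data = {t.name: np.atleast_1d(simulate_vm_hu(t, np.asarray(energies, dtype=float)))
            for t in tissues}
    return pd.DataFrame.from_dict(data, orient="index", columns=list(energies))


# ---------------------------------------------------------------------------
# Phantom geometry and rasterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned circular cylinder (axis along z)."""

    center: tuple[float, float, float]
    radius: float
    half_length: float

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (((x - cx) ** 2 + (y - cy) ** 2) <= self.radius**2) & (
            np.abs(z - cz) <= self.half_length
        )


@dataclass(frozen=True)
class Box:
    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def contains(self, x, y, z):
        (lx, ly, lz), (ux, uy, uz) = self.lower, self.upper
        return (x >= lx) & (x <= ux) & (y >= ly) & (y <= uy) & (z >= lz) & (z <= uz)


@dataclass(frozen=True)
class Region:
    """A labeled phantom region: a shape filled with one tissue.

    Overlapping regions are resolved deterministically: the later-listed
    region wins.
    """

    shape: Ellipsoid | Cylinder | Box
    tissue: str


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom: grid, labeled regions, noise level and seed."""

    grid_shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    regions: tuple[Region, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    origin: tuple[float, float, float] | None = None

    def grid_origin(self) -> tuple[float, float, float]:
        if self.origin is not None:
            return self.origin
        return tuple(
            -(n * s) / 2.0 + s / 2.0 for n, s in zip(self.grid_shape, self.spacing)
        )

    def voxel_coordinates(self):
        o = self.grid_origin()
        axes = [
            o[i] + self.spacing[i] * np.arange(self.grid_shape[i])
            for i in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")


@dataclass
class VMImageSet:
    """Co-registered HU volumes indexed by VM energy on one voxel grid."""

    energies: tuple[float, ...]
    volumes: dict[float, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if list(self.energies) != sorted(set(self.energies)):
            raise ValueError("energies must be strictly increasing")
        shapes = {self.volumes[e].shape for e in self.energies}
        if len(shapes) > 1:
            raise ValueError(f"volumes disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[self.energies[0]].shape

    def volume(self, energy: float) -> np.ndarray:
        try:
            return self.volumes[energy]
        except KeyError:
            raise KeyError(
                f"no VM volume at {energy} keV; available: {list(self.energies)}"
            ) from None


@dataclass
class PhantomRealization:
    """Output of `rasterize_phantom`: images plus ground truth."""

    vm: VMImageSet
    sect: np.ndarray
    labels: np.ndarray
    region_tissues: dict[int, str]
    spec: PhantomSpec = field(repr=False, default=None)


def rasterize_phantom(
    spec: PhantomSpec,
    tissues: Sequence[TissueSurrogate],
    energies: Sequence[float] = DEFAULT_VM_ENERGIES,
    include_sect: bool = True,
) -> PhantomRealization:
    """Rasterize a phantom spec into VM volumes, a SECT volume and labels.

    Each voxel's noiseless HU is its tissue's simulated HU at each energy.
    Gaussian noise of sd ``spec.noise_sd`` is added per voxel with the
    spec's fixed seed; the noise field is shared across VM energies (all VM
    images are synthesized from one spectral acquisition, so their noise is
    strongly correlated -- independent noise would make the two-channel RED
    combination amplify it unphysically), while the 120 kVp SECT volume, a
    separate acquisition, gets its own independent field.  Unlabeled voxels
    are air (-1000 HU).
    """
    by_name = {t.name: t for t in tissues}
    for region in spec.regions:
        if region.tissue not in by_name:
            raise KeyError(f"region tissue {region.tissue!r} not in library")
    x, y, z = spec.voxel_coordinates()
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    for i, region in enumerate(spec.regions, start=1):
        labels[region.shape.contains(x, y, z)] = i
    region_tissues = {i: r.tissue for i, r in enumerate(spec.regions, start=1)}

    energies = tuple(float(e) for e in energies)
    rng = np.random.default_rng(spec.seed)
    vm_noise = rng.normal(0.0, 1.0, size=spec.grid_shape) if spec.noise_sd > 0 else 0.0
    volumes: dict[float, np.ndarray] = {}
    for e in energies:
        vol = np.full(spec.grid_shape, AIR_HU)
        for i, name in region_tissues.items():
            vol[labels == i] = simulate_vm_hu(by_name[name], e)
        if spec.noise_sd > 0:
            vol = vol + spec.noise_sd * vm_noise
        volumes[e] = vol
    vm = VMImageSet(energies=energies, volumes=volumes,
                    spacing=spec.spacing, origin=spec.grid_origin())

    sect = None
    if include_sect:
        sect = np.full(spec.grid_shape, AIR_HU)
        for i, name in region_tissues.items():
            sect[labels == i] = simulate_sect_hu(by_name[name])
        if spec.noise_sd > 0:
            sect = sect + rng.normal(0.0, spec.noise_sd, size=sect.shape)
    return PhantomRealization(vm=vm, sect=sect, labels=labels,
                              region_tissues=region_tissues, spec=spec)


def pediatric_phantom_spec(
    grid_shape: tuple[int, int, int] = (96, 96, 48),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    noise_sd: float = 10.0,
    seed: int = 0,
) -> PhantomSpec:
    """Four-region thorax-like phantom (body / lung / spine / tumor).

    Region tissues follow the anchor mapping used for segmentation-based
    conversion: soft body = HE Blood 40, lung = LN-300, spine = 50% CaCO3,
    tumor = HE Blood 100.  The tumor sphere doubles as the PTV; it sits at
    the anterior edge of the lung so that a +45 degree field crosses the
    full lung thickness while a -45 degree field sees soft tissue only,
    and both fields' target WEPL intervals fall inside the dose engine's
    energy band.
    """
    ext = [n * s for n, s in zip(grid_shape, spacing)]
    sx, sy, sz = ext[0] / 192.0, ext[1] / 192.0, ext[2] / 96.0
    regions = (
        Region(Ellipsoid((0.0, 0.0, 0.0), (85 * sx, 80 * sy, 44 * sz)), "HE Blood 40"),
        Region(Ellipsoid((-30 * sx, 5 * sy, 0.0), (28 * sx, 30 * sy, 28 * sz)), "LN-300 lung"),
        Region(Cylinder((0.0, -55 * sy, 0.0), 12 * min(sx, sy), 44 * sz), "50% CaCO3"),
        Region(Ellipsoid((-12 * sx, 23 * sy, 0.0), (12 * sx,) * 3), "HE Blood 100"),
    )
    return PhantomSpec(grid_shape=grid_shape, spacing=spacing, regions=regions,
                       noise_sd=noise_sd, seed=seed)


def write_phantom(real: PhantomRealization, outdir: str | Path, fmt: str = "mhd") -> Path:
    """Write VM volumes, SECT volume and label map plus a JSON manifest.

    ``fmt`` is "mhd" (MetaImage) or "nii" (NIfTI); one file per energy.
    """
    import SimpleITK as sitk

    ext = {"mhd": ".mhd", "nii": ".nii"}[fmt]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _write(arr, name):
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
        img.SetSpacing(tuple(float(s) for s in real.vm.spacing))
        img.SetOrigin(tuple(float(o) for o in real.vm.origin))
        sitk.WriteImage(img, str(outdir / f"{name}{ext}"))

    for e in real.vm.energies:
        _write(real.vm.volume(e), f"vm_{int(e):03d}kev")
    if real.sect is not None:
        _write(real.sect, "sect_120kvp")
    _write(real.labels.astype(np.int16), "labels")
    manifest = {
        "energies_kev": list(real.vm.energies),
        "spacing_mm": list(real.vm.spacing),
        "origin_mm": list(real.vm.origin),
        "seed": real.spec.seed if real.spec else None,
        "noise_sd_hu": real.spec.noise_sd if real.spec else None,
        "region_tissues": real.region_tissues,
        "format": fmt,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
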