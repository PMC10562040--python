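"""Tissue-surrogate library and Bethe-formula reference stopping powers.

The calibration ground truth is a set of tissue surrogates (the inserts of a
Gammex 1467 electron-density phantom) with known elemental composition,
relative electron density (RED) and reference proton stopping-power ratio
(SPR).  Reference SPRs are computed with the Bethe stopping-power formula,

    SPR = RED * [ln(2 m_e c^2 beta^2 / (I (1 - beta^2))) - beta^2]
              / [ln(2 m_e c^2 beta^2 / (I_w (1 - beta^2))) - beta^2],

with the tissue mean excitation energy I obtained from the elemental
I-values by Bragg additivity.  No shell, density-effect or Barkas
corrections are applied; over the clinical energy range those terms cancel
almost exactly in the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .constants import (
    DEFAULT_PROTON_ENERGY_MEV,
    ELECTRON_REST_ENERGY_MEV,
    ELEMENTS,
    I_WATER,
    PROTON_REST_ENERGY_MEV,
    WATER_COMPOSITION,
    WATER_Z_OVER_A,
)

__all__ = [
    "TissueSurrogate",
    "BetheConstants",
    "mean_excitation_energy",
    "reference_spr",
    "beta_squared",
    "load_gammex_library",
]

_FIXTURE = "gammex1467_inserts_synthetic.csv"


class TissueConfigurationError(ValueError):
    """Raised when a tissue definition is inconsistent or incomplete."""


@dataclass(frozen=True)
class TissueSurrogate:
    """A tissue surrogate with known composition and reference quantities.

    Parameters
    ----------
    name : str
        Insert identifier, e.g. ``"HE Cortical Bone"``.
    elemental_fractions : mapping of element symbol to mass fraction
        Must sum to 1 within 1e-6.
    mass_density : float
        Physical density in g/cm^3.
    reference_red : float
        Electron density relative to water.
    reference_spr : float
        Proton stopping-power ratio relative to water.
    group : str
        One of ``{"lung", "soft", "bone"}``.
    """

    name: str
    elemental_fractions: Mapping[str, float]
    mass_density: float
    reference_red: float
    reference_spr: float
    group: str

    def __post_init__(self) -> None:
        total = sum(self.elemental_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise TissueConfigurationError(
                f"{self.name}: mass fractions sum to {total!r}, expected 1"
            )
        if self.reference_red <= 0:
            raise TissueConfigurationError(f"{self.name}: reference_red must be > 0")
        if self.group not in {"lung", "soft", "bone"}:
            raise TissueConfigurationError(f"{self.name}: unknown group {self.group!r}")

    def electron_fractions(self) -> dict[str, float]:
        """Fraction of electrons contributed by each element (sums to 1)."""
        num = {}
        for el, w in self.elemental_fractions.items():
            if el not in ELEMENTS:
                raise TissueConfigurationError(
                    f"{self.name}: unknown element {el!r} (no Z/A data)"
                )
            z, a, _ = ELEMENTS[el]
            num[el] = w * z / a
        tot = sum(num.values())
        return {el: v / tot for el, v in num.items()}

    @property
    def z_over_a(self) -> float:
        """Electrons per atomic mass unit of the mixture."""
        return sum(
            w * ELEMENTS[el][0] / ELEMENTS[el][1]
            for el, w in self.elemental_fractions.items()
        )


def _default_i_values() -> dict[str, float]:
    return {el: i for el, (_, _, i) in ELEMENTS.items()}


@dataclass(frozen=True)
class BetheConstants:
    """Constants entering the Bethe stopping-power ratio.

    ``proton_kinetic_energy`` defaults to 100 MeV (mid-range of clinical
    energies); moving it anywhere in 80-120 MeV changes any library
    tissue's reference SPR by <0.2% of its default value.
    """

    proton_kinetic_energy: float = DEFAULT_PROTON_ENERGY_MEV
    electron_rest_energy: float = ELECTRON_REST_ENERGY_MEV
    water_i_value: float = I_WATER
    element_i_values: Mapping[str, float] = field(default_factory=_default_i_values)

    def __post_init__(self) -> None:
        if self.water_i_value <= 0 or any(
            v <= 0 for v in self.element_i_values.values()
        ):
            raise TissueConfigurationError("I-values must be positive")
        b2 = beta_squared(self.proton_kinetic_energy)
        if not 0.0 < b2 < 1.0:
            raise TissueConfigurationError(
                f"beta^2 = {b2} out of (0, 1) at {self.proton_kinetic_energy} MeV"
            )


def beta_squared(kinetic_energy_mev: float) -> float:
    """Relativistic beta^2 of a proton with the given kinetic energy."""
    gamma = 1.0 + kinetic_energy_mev / PROTON_REST_ENERGY_MEV
    return 1.0 - 1.0 / (gamma * gamma)


def mean_excitation_energy(
    tissue: TissueSurrogate, constants: BetheConstants | None = None
) -> float:
    """Mean excitation energy I (eV) of a mixture via Bragg additivity.

    ln I = sum(w_i Z_i/A_i ln I_i) / sum(w_i Z_i/A_i).
    """
    constants = constants or BetheConstants()
    acc = 0.0
    for el, lam in tissue.electron_fractions().items():
        if el not in constants.element_i_values:
            raise TissueConfigurationError(
                f"{tissue.name}: no I-value configured for element {el!r}"
            )
        acc += lam * math.log(constants.element_i_values[el])
    return math.exp(acc)


def _stopping_number(i_value_ev: float, constants: BetheConstants) -> float:
    b2 = beta_squared(constants.proton_kinetic_energy)
    arg = 2.0 * constants.electron_rest_energy * 1e6 * b2 / (i_value_ev * (1.0 - b2))
    if arg <= 1.0:
        raise ValueError(
            f"Bethe bracket nonpositive: I = {i_value_ev} eV too large at "
            f"{constants.proton_kinetic_energy} MeV"
        )
    return math.log(arg) - b2


def stopping_factor(
    tissue: TissueSurrogate, constants: BetheConstants | None = None
) -> float:
    """Ratio SPR/RED from the Bethe formula (the composition-only factor)."""
    constants = constants or BetheConstants()
    i_t = mean_excitation_energy(tissue, constants)
    return _stopping_number(i_t, constants) / _stopping_number(
        constants.water_i_value, constants
    )


def reference_spr(
    tissue: TissueSurrogate, constants: BetheConstants | None = None
) -> float:
    """Bethe stopping-power ratio of ``tissue`` relative to water."""
    return tissue.reference_red * stopping_factor(tissue, constants)


def _water_surrogate() -> TissueSurrogate:
    return TissueSurrogate(
        name="water",
        elemental_fractions=dict(WATER_COMPOSITION),
        mass_density=1.0,
        reference_red=1.0,
        reference_spr=1.0,
        group="soft",
    )


def load_gammex_library(
    constants: BetheConstants | None = None,
) -> list[TissueSurrogate]:
    """Load the bundled synthetic Gammex 1467 insert library.

    The CSV stores compositions and published reference SPRs; the reference
    RED of each insert is derived here as reference_spr / stopping_factor so
    that `reference_spr` recomputed from the composition reproduces the
    published value by construction (the vendor REDs are not deposited).
    """
    constants = constants or BetheConstants()
    path = resources.files("spectral_spr.data").joinpath(_FIXTURE)
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    tissues = []
    element_cols = [c for c in df.columns if c in ELEMENTS]
    for _, row in df.iterrows():
        fractions = {
            el: float(row[el]) / 100.0 for el in element_cols if float(row[el]) > 0
        }
        probe = TissueSurrogate(
            name=str(row["name"]),
            elemental_fractions=fractions,
            mass_density=1.0,
            reference_red=1.0,
            reference_spr=float(row["reference_spr"]),
            group=str(row["group"]),
        )
        red = float(row["reference_spr"]) / stopping_factor(probe, constants)
        density = red * WATER_Z_OVER_A / probe.z_over_a
        tissues.append(
            TissueSurrogate(
                name=probe.name,
                elemental_fractions=fractions,
                mass_density=density,
                reference_red=red,
                reference_spr=probe.reference_spr,
                group=probe.group,
            )
        )
    return tissues
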