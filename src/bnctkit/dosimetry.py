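"""Four-component physical dose and photon-equivalent dose model.

A mixed epithermal/thermal neutron field deposits dose through four physical
channels: boron capture (D_B), nitrogen capture (D_N), proton recoil on
hydrogen (D_H) and gamma contamination of the beam (D_g).  The physical dose
is their plain sum; the biologically weighted ("photon-equivalent", Gy-Eq)
dose applies a compound-specific boron weighting factor (CBE) to D_B and
fixed relative biological effectiveness factors to D_N and D_H:

    Gy-Eq = D_B * CBE + D_N * RBE_N + D_H * RBE_H + D_g

Beam transport (spectrum, depth correction) is out of scope: beam parameters
are taken as already site-corrected inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence, Union

import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .rounding import round_half_up

__all__ = [
    "BeamSpec",
    "KermaSet",
    "DoseComponents",
    "WeightSet",
    "DoseScenario",
    "DEFAULT_COMPONENT_SPLIT",
    "DEFAULT_BORON_KERMA",
    "boron_physical_dose",
    "nonboron_dose_components",
    "beam_dose_components",
    "total_physical_dose",
    "photon_equivalent_dose",
    "effective_boron_concentration",
    "dose_report",
]

#: Default split of the boron-free beam dose into (nitrogen, hydrogen, gamma)
#: fractions.  Solved so that 1.0 Gy of boron-free beam maps to 1.7 Gy-Eq with
#: RBE_N = RBE_H = 3.0, i.e. f_N + f_H = 0.35 and f_gamma = 0.65; the N/H
#: subdivision is irrelevant whenever RBE_N == RBE_H and is taken as equal.
DEFAULT_COMPONENT_SPLIT: tuple[float, float, float] = (0.175, 0.175, 0.65)

#: Boron kerma coefficient, Gy per (ug 10B / g tissue) per (n / cm^2).
#: Literature thermal-fluence value: sigma(10B(n,alpha)7Li) = 3837 b with
#: ~2.33 MeV deposited locally gives ~8.66e-14.  Configurable; nothing in the
#: reported acceptance math depends on the specific value.
DEFAULT_BORON_KERMA: float = 8.66e-14


def _require_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class BeamSpec:
    """Neutron beam operating point for one exposure.

    Parameters
    ----------
    flux : float
        Neutron flux at the sample, n/cm^2/s (> 0).
    duration : float
        Irradiation duration in seconds (>= 0).
    nonboron_dose_rate : float
        Total boron-free physical dose rate (N + H + gamma), Gy/s (>= 0).
    component_split : tuple
        Fractions (f_N, f_H, f_gamma) of the boron-free dose; must sum to 1.
    """

    flux: float
    duration: float
    nonboron_dose_rate: float
    component_split: tuple[float, float, float] = DEFAULT_COMPONENT_SPLIT

    def __post_init__(self) -> None:
        if not (math.isfinite(self.flux) and self.flux > 0):
            raise InvalidInputError(f"flux must be > 0, got {self.flux!r}")
        _require_finite_nonneg("duration", self.duration)
        _require_finite_nonneg("nonboron_dose_rate", self.nonboron_dose_rate)
        split = tuple(float(f) for f in self.component_split)
        if len(split) != 3 or any(not (0.0 <= f <= 1.0) for f in split):
            raise InvalidInputError(f"component_split fractions must lie in [0,1]: {split!r}")
        if abs(sum(split) - 1.0) > 1e-9:
            raise InvalidInputError(f"component_split must sum to 1 +/- 1e-9: {split!r}")
        object.__setattr__(self, "component_split", split)

    @property
    def fluence(self) -> float:
        """Time-integrated fluence, n/cm^2."""
        return self.flux * self.duration

    @property
    def nonboron_dose(self) -> float:
        """Total boron-free physical dose over the exposure, Gy."""
        return self.nonboron_dose_rate * self.duration


@dataclass(frozen=True)
class KermaSet:
    """Flux-to-dose conversion constants."""

    boron_coefficient: float = DEFAULT_BORON_KERMA

    def __post_init__(self) -> None:
        if not (math.isfinite(self.boron_coefficient) and self.boron_coefficient > 0):
            raise InvalidInputError(
                f"boron_coefficient must be > 0, got {self.boron_coefficient!r}"
            )


@dataclass(frozen=True)
class DoseComponents:
    """The four physical dose terms for one tissue/exposure, each in Gy."""

    d_boron: float
    d_nitrogen: float
    d_hydrogen: float
    d_gamma: float

    def __post_init__(self) -> None:
        for name in ("d_boron", "d_nitrogen", "d_hydrogen", "d_gamma"):
            _require_finite_nonneg(name, getattr(self, name))

    def scaled(self, factor: float) -> "DoseComponents":
        """All four components multiplied by ``factor`` (e.g. a time rescale)."""
        return DoseComponents(
            self.d_boron * factor,
            self.d_nitrogen * factor,
            self.d_hydrogen * factor,
            self.d_gamma * factor,
        )


@dataclass(frozen=True)
class WeightSet:
    """Biological weighting factors for one compound/tissue context.

    ``cbe`` weights the boron dose in the tissue of interest (tumor in the
    default reports); ``cbe_brain`` is the normal-brain boron weight, used for
    scenarios flagged as brain.  The shipped brain default (1.35) is the
    published normal-brain value for the clinical amino-acid carrier and is
    also applied, flagged, to compounds whose own brain weight is unknown.
    """

    cbe: float
    rbe_n: float = 3.0
    rbe_h: float = 3.0
    cbe_brain: float = 1.35

    def __post_init__(self) -> None:
        for name in ("cbe", "rbe_n", "rbe_h", "cbe_brain"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidInputError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class DoseScenario:
    """One tissue row of a dose report: measured boron level and its usable fraction."""

    tissue: str
    boron_mean: float
    boron_sd: float = 0.0
    contribution_fraction: float = 1.0
    compound: Union[str, None] = None
    use_brain_cbe: bool = False

    def __post_init__(self) -> None:
        _require_finite_nonneg("boron_mean", self.boron_mean)
        _require_finite_nonneg("boron_sd", self.boron_sd)
        if not (0.0 < self.contribution_fraction <= 1.0):
            raise InvalidInputError(
                f"contribution_fraction must lie in (0, 1], got {self.contribution_fraction!r}"
            )


def boron_physical_dose(concentration: float, beam: BeamSpec, kerma: KermaSet) -> float:
    """Boron capture dose D_B = kerma * concentration * fluence, in Gy.

    Linear in concentration, flux and duration.  ``concentration`` is in
    ug 10B per g of tissue.
    """
    _require_finite_nonneg("concentration", concentration)
    return kerma.boron_coefficient * concentration * beam.fluence


def nonboron_dose_components(beam: BeamSpec) -> tuple[float, float, float]:
    """(D_N, D_H, D_gamma) for the boron-free beam over the full exposure, Gy."""
    f_n, f_h, f_g = beam.component_split
    total = beam.nonboron_dose
    return (f_n * total, f_h * total, f_g * total)


def beam_dose_components(
    concentration: float, beam: BeamSpec, kerma: KermaSet
) -> DoseComponents:
    """All four physical dose components for a tissue at a given boron level."""
    d_n, d_h, d_g = nonboron_dose_components(beam)
    return DoseComponents(
        d_boron=boron_physical_dose(concentration, beam, kerma),
        d_nitrogen=d_n,
        d_hydrogen=d_h,
        d_gamma=d_g,
    )


def total_physical_dose(components: DoseComponents) -> float:
    """Plain sum of the four physical dose terms, Gy."""
    return (
        components.d_boron
        + components.d_nitrogen
        + components.d_hydrogen
        + components.d_gamma
    )


def photon_equivalent_dose(
    components: DoseComponents, weights: WeightSet, brain: bool = False
) -> float:
    """Biologically weighted dose in Gy-Eq.

    ``D_B * CBE + D_N * RBE_N + D_H * RBE_H + D_gamma``; equals the physical
    dose whenever all weights are 1.  With ``brain=True`` the normal-brain
    boron weight is used instead of the tumor one.
    """
    cbe = weights.cbe_brain if brain else weights.cbe
    return (
        components.d_boron * cbe
        + components.d_nitrogen * weights.rbe_n
        + components.d_hydrogen * weights.rbe_h
        + components.d_gamma
    )


Which = Literal["mean", "mean-sd", "mean+sd"]

_WHICH_SIGN = {"mean": 0.0, "mean-sd": -1.0, "mean+sd": 1.0}


def effective_boron_concentration(scenario: DoseScenario, which: Which = "mean") -> float:
    """Boron concentration entering the dose model, ug B/g.

    Applies the scenario's contribution fraction (the share of the measured
    tissue boron assumed to actually reach cells, e.g. 0.25 for local
    infusion) to mean, mean-SD or mean+SD, flooring at zero.
    """
    try:
        sign = _WHICH_SIGN[which]
    except KeyError:
        raise InvalidInputError(f"which must be one of {sorted(_WHICH_SIGN)}, got {which!r}")
    concentration = max(scenario.boron_mean + sign * scenario.boron_sd, 0.0)
    return scenario.contribution_fraction * concentration


def dose_report(
    scenarios: Sequence[DoseScenario],
    beam: BeamSpec,
    kerma: KermaSet,
    weights: Union[WeightSet, Mapping[str, WeightSet]],
    round_to: Union[int, None] = None,
) -> pd.DataFrame:
    """Physical and photon-equivalent dose table at mean, mean-SD and mean+SD.

    ``weights`` may be a single :class:`WeightSet` or a mapping from compound
    label to :class:`WeightSet`; a scenario naming a compound absent from the
    mapping raises :class:`~bnctkit.errors.ConfigurationError`.  Brain-flagged
    scenarios use ``cbe_brain`` and are marked in the ``brain_cbe_used``
    column.  ``round_to`` rounds the reported dose columns half-up.
    """
    rows = []
    for scenario in scenarios:
        if isinstance(weights, Mapping):
            key = scenario.compound
            if key not in weights:
                raise ConfigurationError(
                    f"no WeightSet configured for compound {key!r} (tissue {scenario.tissue!r})"
                )
            wset = weights[key]
        else:
            wset = weights
        for which in ("mean", "mean-sd", "mean+sd"):
            conc = effective_boron_concentration(scenario, which)  # type: ignore[arg-type]
            comps = beam_dose_components(conc, beam, kerma)
            physical = total_physical_dose(comps)
            gy_eq = photon_equivalent_dose(comps, wset, brain=scenario.use_brain_cbe)
            if round_to is not None:
                physical = round_half_up(physical, round_to)
                gy_eq = round_half_up(gy_eq, round_to)
            rows.append(
                {
                    "tissue": scenario.tissue,
                    "compound": scenario.compound,
                    "statistic": which,
                    "effective_boron_ug_g": conc,
                    "d_boron_gy": comps.d_boron,
                    "physical_dose_gy": physical,
                    "photon_equivalent_gy_eq": gy_eq,
                    "cbe_used": wset.cbe_brain if scenario.use_brain_cbe else wset.cbe,
                    "brain_cbe_used": scenario.use_brain_cbe,
                }
            )
    columns = [
        "tissue",
        "compound",
        "statistic",
        "effective_boron_ug_g",
        "d_boron_gy",
        "physical_dose_gy",
        "photon_equivalent_gy_eq",
        "cbe_used",
        "brain_cbe_used",
    ]
    return pd.DataFrame(rows, columns=columns)
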