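"""Synthetic dataset generator mirroring the structure of the real experiments.

Generates (a) clonogenic colony counts under a known LQ truth with boron-
dependent photon-equivalent kill dose, (b) per-animal tissue boron
concentrations with configured group means/SDs, and (c) per-animal survival
times with configured group medians/ranges — all from one integer seed, so
every analysis stage has a parameter-recovery oracle.

One global seed is expanded into independent per-stage substreams
(SeedSequence spawn keys), so regenerating one stage never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assay import ColonyCountRecord
from .biodistribution import TissueBoronRecord
from .dosimetry import BeamSpec, KermaSet, WeightSet
from .errors import ConfigurationError
from .radiobiology import DoseSFPoint, LQParams
from .survival import SurvivalRecord

__all__ = [
    "AssayCondition",
    "BiodistTarget",
    "SurvivalTarget",
    "SyntheticConfig",
    "boron_dose_rate_per_min",
    "nonboron_rates_per_min",
    "equivalent_dose_rate_per_min",
    "true_sf",
    "true_compound_points",
    "true_photon_points",
    "gen_colony_assay",
    "gen_photon_assay",
    "gen_biodistribution",
    "gen_survival_study",
    "write_dataset",
    "config_to_dict",
    "config_from_dict",
]

_STREAM_COLONY, _STREAM_PHOTON, _STREAM_BIODIST, _STREAM_SURVIVAL = range(4)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class AssayCondition:
    """One exposure arm of the synthetic colony assay.

    ``cellular_boron`` is the boron concentration seen by the cells (ug 10B/g)
    and ``cbe`` the true weighting applied to the resulting boron dose when
    composing the photon-equivalent kill dose.
    """

    condition_id: str
    cellular_boron: float
    cbe: float
    compound: Optional[str] = None
    medium_boron: float = 10.0
    exposure_h: float = 2.5


@dataclass(frozen=True)
class BiodistTarget:
    compound: str
    route: str
    dose: float
    time_h: float
    tissue: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class SurvivalTarget:
    group: str
    median: float
    range_min: float
    range_max: float
    n: int


def _default_conditions() -> tuple:
    return (
        AssayCondition("irradiated", 0.0, 1.0, None, medium_boron=0.0, exposure_h=0.0),
        AssayCondition("bpa-2.5h", 17.0, 2.02, "BPA", exposure_h=2.5),
        AssayCondition("badb-2.5h", 20.0, 1.75, "BADB", exposure_h=2.5),
        AssayCondition("badb-24h", 7.4, 4.66, "BADB", exposure_h=24.0),
    )


def _default_biodist_targets() -> tuple:
    badb = [("BADB", "ced", 1.2)]
    bpa = [("BPA", "iv", 12.0)]
    rows = []
    for (compound, route, dose), time_h, tissue, mean, sd, n in [
        (badb[0], 2.0, "tumor", 32.8, 16.7, 5),
        (badb[0], 2.0, "brain", 1.0, 0.8, 5),
        (badb[0], 2.0, "blood", 0.5, 0.2, 5),
        (badb[0], 6.0, "tumor", 45.8, 16.5, 5),
        (badb[0], 6.0, "brain", 1.3, 0.7, 5),
        (badb[0], 6.0, "blood", 0.4, 0.1, 5),
        (badb[0], 24.0, "tumor", 25.1, 26.6, 3),
        (badb[0], 24.0, "brain", 0.2, 0.1, 3),
        (badb[0], 24.0, "blood", 0.2, 0.0, 3),
        (bpa[0], 2.0, "tumor", 17.8, 1.4, 4),
        (bpa[0], 2.0, "brain", 4.3, 0.9, 4),
        (bpa[0], 2.0, "blood", 8.7, 3.0, 4),
        (bpa[0], 6.0, "tumor", 13.4, 2.1, 4),
        (bpa[0], 6.0, "brain", 3.7, 0.6, 4),
        (bpa[0], 6.0, "blood", 6.1, 1.4, 4),
    ]:
        rows.append(BiodistTarget(compound, route, dose, time_h, tissue, mean, sd, n))
    return tuple(rows)


def _default_survival_targets() -> tuple:
    return (
        SurvivalTarget("control", 26.5, 25, 28, 6),
        SurvivalTarget("irradiated", 28, 26, 30, 5),
        SurvivalTarget("badb-only", 28, 27, 29, 5),
        SurvivalTarget("bpa-bnct", 34, 33, 36, 6),
        SurvivalTarget("badb-bnct", 31, 29, 35, 8),
        SurvivalTarget("badb-bpa-bnct", 38, 36, 40, 7),
    )


@dataclass
class SyntheticConfig:
    """Everything the generator needs; the seed fixes all randomness."""

    seed: int = 0
    lq_truth: LQParams = field(default_factory=lambda: LQParams(alpha=0.3, beta=0.03))
    beam: BeamSpec = field(
        default_factory=lambda: BeamSpec(
            flux=7.0e8, duration=3600.0, nonboron_dose_rate=1.0 / 3600.0
        )
    )
    kerma: KermaSet = field(default_factory=KermaSet)
    true_weights: WeightSet = field(default_factory=lambda: WeightSet(cbe=4.66))
    assay_conditions: tuple = field(default_factory=_default_conditions)
    irradiation_minutes: tuple = (10.0, 30.0, 60.0)
    photon_doses: tuple = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)
    dishes_per_condition: int = 3
    cells_per_dish: int = 2000
    plating_efficiency: float = 0.6
    biodist_targets: tuple = field(default_factory=_default_biodist_targets)
    survival_targets: tuple = field(default_factory=_default_survival_targets)

    def __post_init__(self) -> None:
        if self.dishes_per_condition < 1 or self.cells_per_dish < 1:
            raise ConfigurationError("dishes_per_condition and cells_per_dish must be >= 1")
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise ConfigurationError("plating_efficiency must lie in (0, 1]")


# ---------------------------------------------------------------------------
# dose bookkeeping (per minute of irradiation, rates constant over time)


def boron_dose_rate_per_min(concentration: float, beam: BeamSpec, kerma: KermaSet) -> float:
    """Boron physical dose rate in Gy/min at a given cellular concentration."""
    return kerma.boron_coefficient * concentration * beam.flux * 60.0


def nonboron_rates_per_min(beam: BeamSpec) -> tuple[float, float, float]:
    """(N, H, gamma) physical dose rates in Gy/min."""
    f_n, f_h, f_g = beam.component_split
    rate = beam.nonboron_dose_rate * 60.0
    return (f_n * rate, f_h * rate, f_g * rate)


def equivalent_dose_rate_per_min(config: SyntheticConfig, condition: AssayCondition) -> float:
    """Photon-equivalent kill dose rate (Gy-Eq/min) for one assay condition."""
    w = config.true_weights
    r_n, r_h, r_g = nonboron_rates_per_min(config.beam)
    r_b = boron_dose_rate_per_min(condition.cellular_boron, config.beam, config.kerma)
    return r_b * condition.cbe + r_n * w.rbe_n + r_h * w.rbe_h + r_g


def true_sf(config: SyntheticConfig, condition: AssayCondition, minutes: float) -> float:
    """Noise-free surviving fraction after ``minutes`` of irradiation."""
    dose_eq = equivalent_dose_rate_per_min(config, condition) * minutes
    lq = config.lq_truth
    return math.exp(-lq.alpha * dose_eq - lq.beta * dose_eq**2)


def true_compound_points(
    config: SyntheticConfig, condition: AssayCondition
) -> list[DoseSFPoint]:
    """Exact (irradiation time in minutes, SF) points — the noiseless limit."""
    return [
        DoseSFPoint(dose=minutes, sf=true_sf(config, condition, minutes),
                    condition_id=condition.condition_id)
        for minutes in config.irradiation_minutes
    ]


def true_photon_points(config: SyntheticConfig) -> list[DoseSFPoint]:
    """Exact photon (dose, SF) points from the LQ truth."""
    lq = config.lq_truth
    return [
        DoseSFPoint(dose=d, sf=math.exp(-lq.alpha * d - lq.beta * d**2), condition_id="xray")
        for d in config.photon_doses
    ]


# ---------------------------------------------------------------------------
# generators


def _binomial_dishes(
    rng: np.random.Generator, config: SyntheticConfig, survival_prob: float
) -> tuple:
    p = config.plating_efficiency * survival_prob
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"colony probability {p!r} outside [0, 1]")
    counts = rng.binomial(config.cells_per_dish, p, size=config.dishes_per_condition)
    return tuple((config.cells_per_dish, int(c)) for c in counts)


def gen_colony_assay(config: SyntheticConfig) -> list[ColonyCountRecord]:
    """Colony counts: an unirradiated control plus every condition x duration.

    Colonies per dish are Binomial(cells_per_dish, PE * SF_true), with SF_true
    derived from the photon-equivalent dose accumulated over the irradiation.
    """
    rng = _rng(config.seed, _STREAM_COLONY)
    records = [
        ColonyCountRecord(
            condition_id="control",
            dishes=_binomial_dishes(rng, config, 1.0),
            irradiation_duration=0.0,
        )
    ]
    for condition in config.assay_conditions:
        for minutes in config.irradiation_minutes:
            sf = true_sf(config, condition, minutes)
            if not (0.0 < sf <= 1.0):
                raise ConfigurationError(
                    f"true SF {sf!r} outside (0, 1] for {condition.condition_id!r}"
                )
            records.append(
                ColonyCountRecord(
                    condition_id=condition.condition_id,
                    compound=condition.compound,
                    medium_boron=condition.medium_boron,
                    exposure_duration=condition.exposure_h,
                    irradiation_duration=minutes,
                    dishes=_binomial_dishes(rng, config, sf),
                )
            )
    return records


def gen_photon_assay(config: SyntheticConfig) -> pd.DataFrame:
    """Reference photon colony counts, one row per dish (dose 0 = control)."""
    rng = _rng(config.seed, _STREAM_PHOTON)
    lq = config.lq_truth
    rows = []
    for dose in (0.0, *config.photon_doses):
        sf = math.exp(-lq.alpha * dose - lq.beta * dose**2)
        for dish, (seeded, colonies) in enumerate(_binomial_dishes(rng, config, sf)):
            rows.append(
                {"dose_gy": dose, "dish": dish, "cells_seeded": seeded, "colonies": colonies}
            )
    return pd.DataFrame(rows)


def gen_biodistribution(config: SyntheticConfig) -> list[TissueBoronRecord]:
    """Per-animal concentrations, lognormal with moments matched per group.

    The lognormal keeps concentrations strictly nonnegative even for groups
    whose SD exceeds the mean; sd = 0 produces identical animals at the mean.
    """
    rng = _rng(config.seed, _STREAM_BIODIST)
    records = []
    for target in config.biodist_targets:
        if target.sd < 0:
            raise ConfigurationError(f"negative sd in biodistribution target {target!r}")
        if target.mean < 0:
            raise ConfigurationError(f"negative mean in biodistribution target {target!r}")
        if target.sd == 0 or target.mean == 0:
            values = np.full(target.n, target.mean)
        else:
            cv2 = (target.sd / target.mean) ** 2
            sigma2 = math.log1p(cv2)
            mu = math.log(target.mean) - sigma2 / 2.0
            values = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=target.n)
        for i, value in enumerate(values):
            records.append(
                TissueBoronRecord(
                    animal_id=f"{target.compound}-{target.route}-{target.time_h:g}h-{i + 1}",
                    compound=target.compound,
                    route=target.route,
                    dose=target.dose,
                    time_h=target.time_h,
                    tissue=target.tissue,
                    concentration=float(value),
                )
            )
    return records


def gen_survival_study(config: SyntheticConfig) -> list[SurvivalRecord]:
    """Whole-day survival times from a rounded normal clipped to each range.

    The normal is centred on the target median so the group median matches in
    expectation; a degenerate range (min = max) yields identical animals.
    All generated records are observed deaths (event = 1); censoring is left
    to the consuming estimators.
    """
    rng = _rng(config.seed, _STREAM_SURVIVAL)
    records = []
    for target in config.survival_targets:
        lo, hi = target.range_min, target.range_max
        if not (lo <= target.median <= hi):
            raise ConfigurationError(
                f"median {target.median} outside range [{lo}, {hi}] for {target.group!r}"
            )
        if lo <= 0:
            raise ConfigurationError("survival times must be positive; range_min must be > 0")
        if lo == hi:
            days = np.full(target.n, float(lo))
        else:
            spread = max((hi - lo) / 4.0, 0.5)
            days = np.clip(np.rint(rng.normal(target.median, spread, size=target.n)), lo, hi)
        for i, day in enumerate(days):
            records.append(
                SurvivalRecord(
                    animal_id=f"{target.group}-{i + 1}",
                    group=target.group,
                    time=float(day),
                    event=1,
                )
            )
    return records


# ---------------------------------------------------------------------------
# serialization


def config_to_dict(config: SyntheticConfig) -> dict:
    """JSON-safe dictionary (lossless for everything the pipeline consumes)."""
    return {
        "seed": config.seed,
        "lq_truth": {"alpha": config.lq_truth.alpha, "beta": config.lq_truth.beta},
        "beam": {
            "flux": config.beam.flux,
            "duration": config.beam.duration,
            "nonboron_dose_rate": config.beam.nonboron_dose_rate,
            "component_split": list(config.beam.component_split),
        },
        "kerma": {"boron_coefficient": config.kerma.boron_coefficient},
        "true_weights": dataclasses.asdict(config.true_weights),
        "assay_conditions": [dataclasses.asdict(c) for c in config.assay_conditions],
        "irradiation_minutes": list(config.irradiation_minutes),
        "photon_doses": list(config.photon_doses),
        "dishes_per_condition": config.dishes_per_condition,
        "cells_per_dish": config.cells_per_dish,
        "plating_efficiency": config.plating_efficiency,
        "biodist_targets": [dataclasses.asdict(t) for t in config.biodist_targets],
        "survival_targets": [dataclasses.asdict(t) for t in config.survival_targets],
    }


def config_from_dict(data: dict) -> SyntheticConfig:
    return SyntheticConfig(
        seed=int(data["seed"]),
        lq_truth=LQParams(**data["lq_truth"]),
        beam=BeamSpec(
            flux=data["beam"]["flux"],
            duration=data["beam"]["duration"],
            nonboron_dose_rate=data["beam"]["nonboron_dose_rate"],
            component_split=tuple(data["beam"]["component_split"]),
        ),
        kerma=KermaSet(**data["kerma"]),
        true_weights=WeightSet(**data["true_weights"]),
        assay_conditions=tuple(AssayCondition(**c) for c in data["assay_conditions"]),
        irradiation_minutes=tuple(data["irradiation_minutes"]),
        photon_doses=tuple(data["photon_doses"]),
        dishes_per_condition=int(data["dishes_per_condition"]),
        cells_per_dish=int(data["cells_per_dish"]),
        plating_efficiency=float(data["plating_efficiency"]),
        biodist_targets=tuple(BiodistTarget(**t) for t in data["biodist_targets"]),
        survival_targets=tuple(SurvivalTarget(**t) for t in data["survival_targets"]),
    )


def write_dataset(config: SyntheticConfig, out_dir) -> dict:
    """Write the three CSV inputs plus a provenance manifest; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    colony_rows = []
    for record in gen_colony_assay(config):
        for seeded, colonies in record.dishes:
            colony_rows.append(
                {
                    "condition_id": record.condition_id,
                    "compound": record.compound,
                    "medium_boron_ug_ml": record.medium_boron,
                    "exposure_h": record.exposure_duration,
                    "irradiation_min": record.irradiation_duration,
                    "cells_seeded": seeded,
                    "colonies": colonies,
                }
            )
    paths = {
        "colony_assay": out / "colony_assay.csv",
        "photon_assay": out / "photon_assay.csv",
        "biodistribution": out / "biodistribution.csv",
        "survival": out / "survival.csv",
        "manifest": out / "manifest.json",
    }
    pd.DataFrame(colony_rows).to_csv(paths["colony_assay"], index=False)
    gen_photon_assay(config).to_csv(paths["photon_assay"], index=False)

    from .biodistribution import records_to_frame

    records_to_frame(gen_biodistribution(config)).to_csv(
        paths["biodistribution"], index=False
    )
    pd.DataFrame(
        [
            {"animal_id": r.animal_id, "group": r.group, "time_days": r.time, "event": r.event}
            for r in gen_survival_study(config)
        ]
    ).to_csv(paths["survival"], index=False)
    with open(paths["manifest"], "w") as handle:
        json.dump(config_to_dict(config), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return {k: str(v) for k, v in paths.items()}
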