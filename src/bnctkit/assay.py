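"""Clonogenic-assay and cellular boron-uptake analysis.

Turns raw per-dish colony counts into plating efficiencies and survival
fractions, summarizes cellular uptake replicates, and computes washout
retention rates.  Colony counting semantics (the >= 50 cells per colony rule)
are upstream data-entry conventions, not recomputed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidControlError,
    InvalidInputError,
    SurvivalFractionWarning,
)

__all__ = [
    "ColonyCountRecord",
    "UptakeMeasurement",
    "plating_efficiency",
    "survival_fraction",
    "retention_rate",
    "compare_uptake",
    "read_colony_csv",
    "assay_summary",
]


@dataclass(frozen=True)
class ColonyCountRecord:
    """Colony counts for one exposure condition at one irradiation duration.

    ``dishes`` holds ``(cells_seeded, colonies)`` pairs, one per dish.
    """

    condition_id: str
    dishes: tuple
    compound: Optional[str] = None
    medium_boron: float = 0.0  # ug B/mL
    exposure_duration: float = 0.0  # hours
    irradiation_duration: float = 0.0  # minutes

    def __post_init__(self) -> None:
        dishes = tuple((int(seeded), int(col)) for seeded, col in self.dishes)
        if len(dishes) < 1:
            raise InvalidInputError("a record needs at least one dish")
        for seeded, colonies in dishes:
            if seeded <= 0:
                raise InvalidInputError(f"cells_seeded must be > 0, got {seeded}")
            if colonies < 0 or colonies > seeded:
                raise InvalidInputError(
                    f"colonies must lie in [0, cells_seeded], got {colonies}/{seeded}"
                )
        object.__setattr__(self, "dishes", dishes)
        for name in ("medium_boron", "exposure_duration", "irradiation_duration"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def total_seeded(self) -> int:
        return sum(seeded for seeded, _ in self.dishes)

    @property
    def total_colonies(self) -> int:
        return sum(colonies for _, colonies in self.dishes)


@dataclass(frozen=True)
class UptakeMeasurement:
    """Replicate cellular boron concentrations for one compound/medium/incubation."""

    compound: str
    medium_boron: float  # ug B/mL
    incubation: float  # hours
    replicate_values: tuple  # ug B per 1e9 cells

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.replicate_values)
        if len(values) == 0:
            raise InvalidInputError("replicate_values must be nonempty")
        if any(not math.isfinite(v) or v < 0 for v in values):
            raise InvalidInputError("replicate_values must be finite and >= 0")
        object.__setattr__(self, "replicate_values", values)


def plating_efficiency(record: ColonyCountRecord) -> float:
    """Pooled plating efficiency: total colonies / total cells seeded."""
    seeded = record.total_seeded
    if seeded <= 0:  # unreachable through the type, kept as a contract
        raise InvalidInputError("total cells seeded must be > 0")
    return record.total_colonies / seeded


def survival_fraction(treated: ColonyCountRecord, control: ColonyCountRecord) -> float:
    """Surviving fraction: treated plating efficiency over control's.

    Values above 1 are possible under counting noise and are returned as-is
    with a :class:`SurvivalFractionWarning`.
    """
    pe_control = plating_efficiency(control)
    if pe_control == 0:
        raise InvalidControlError(
            f"control condition {control.condition_id!r} has zero plating efficiency"
        )
    sf = plating_efficiency(treated) / pe_control
    if sf > 1.0:
        warnings.warn(
            f"survival fraction {sf:.4g} > 1 for condition {treated.condition_id!r}",
            SurvivalFractionWarning,
            stacklevel=2,
        )
    return sf


def retention_rate(conc_after_washout: float, conc_at_washout: float) -> float:
    """Percent of cellular boron retained after the washout interval."""
    if not math.isfinite(conc_at_washout) or conc_at_washout <= 0:
        raise InvalidInputError(
            f"concentration at washout must be > 0, got {conc_at_washout!r}"
        )
    if not math.isfinite(conc_after_washout) or conc_after_washout < 0:
        raise InvalidInputError(
            f"concentration after washout must be >= 0, got {conc_after_washout!r}"
        )
    return 100.0 * conc_after_washout / conc_at_washout


def compare_uptake(
    a: UptakeMeasurement, b: UptakeMeasurement, welch: bool = False
) -> tuple[float, float]:
    """Two-sided t-test between two uptake replicate sets.

    Pooled-variance (Student) by default; ``welch=True`` drops the equal
    variance assumption.  Returns ``(t, p)``.
    """
    if len(a.replicate_values) < 2 or len(b.replicate_values) < 2:
        raise InsufficientDataError("need >= 2 replicates per group for a t-test")
    result = stats.ttest_ind(a.replicate_values, b.replicate_values, equal_var=not welch)
    t, p = float(result.statistic), float(result.pvalue)
    if math.isnan(t):  # both groups constant and equal
        return 0.0, 1.0
    return t, p


# ---------------------------------------------------------------------------
# delimited-text interface

#: Required columns of the colony CSV, one row per dish.
COLONY_CSV_COLUMNS = (
    "condition_id",
    "compound",
    "medium_boron_ug_ml",
    "exposure_h",
    "irradiation_min",
    "cells_seeded",
    "colonies",
)


def read_colony_csv(path) -> list[ColonyCountRecord]:
    """Read per-dish colony counts (one row per dish) into records.

    Rows are grouped into one record per (condition_id, irradiation_min).
    """
    frame = pd.read_csv(path)
    missing = [c for c in COLONY_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"colony CSV is missing columns: {missing}")
    records = []
    for (condition, minutes), group in frame.groupby(
        ["condition_id", "irradiation_min"], sort=True
    ):
        first = group.iloc[0]
        compound = first["compound"]
        records.append(
            ColonyCountRecord(
                condition_id=str(condition),
                compound=None if pd.isna(compound) else str(compound),
                medium_boron=float(first["medium_boron_ug_ml"]),
                exposure_duration=float(first["exposure_h"]),
                irradiation_duration=float(minutes),
                dishes=tuple(zip(group["cells_seeded"], group["colonies"])),
            )
        )
    return records


def assay_summary(
    records: Sequence[ColonyCountRecord], control_id: str = "control"
) -> pd.DataFrame:
    """Tidy per-condition summary: plating efficiency and survival fraction.

    The control is the record whose ``condition_id`` equals ``control_id``
    (unique, required); its own row carries SF = 1 by construction.
    """
    controls = [r for r in records if r.condition_id == control_id]
    if len(controls) != 1:
        raise InvalidInputError(
            f"expected exactly one control record with condition_id {control_id!r}, "
            f"found {len(controls)}"
        )
    control = controls[0]
    rows = []
    for record in records:
        rows.append(
            {
                "condition_id": record.condition_id,
                "compound": record.compound,
                "medium_boron_ug_ml": record.medium_boron,
                "exposure_h": record.exposure_duration,
                "irradiation_min": record.irradiation_duration,
                "n_dishes": len(record.dishes),
                "cells_seeded": record.total_seeded,
                "colonies": record.total_colonies,
                "plating_efficiency": plating_efficiency(record),
                "survival_fraction": survival_fraction(record, control),
            }
        )
    return pd.DataFrame(rows)
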