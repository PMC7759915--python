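"""Tissue boron biodistribution summaries and tumor-to-normal ratios."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import InvalidInputError
from .rounding import round_half_up

__all__ = [
    "TissueBoronRecord",
    "records_to_frame",
    "summarize",
    "tumor_ratios",
    "apply_detection_floor",
    "GROUP_KEYS",
]

#: Grouping key of a biodistribution summary row.
GROUP_KEYS = ("compound", "route", "time_h", "tissue")


@dataclass(frozen=True)
class TissueBoronRecord:
    """Boron concentration in one tissue of one animal at one time point."""

    animal_id: str
    compound: str
    route: str  # "iv" or "ced"
    dose: float  # mg B/kg body weight
    time_h: float  # hours after administration ended
    tissue: str
    concentration: float  # ug B/g

    def __post_init__(self) -> None:
        if self.route not in ("iv", "ced"):
            raise InvalidInputError(f"route must be 'iv' or 'ced', got {self.route!r}")
        for name in ("dose", "time_h", "concentration"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")


def records_to_frame(records: Sequence[TissueBoronRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "compound": r.compound,
                "route": r.route,
                "dose_mg_b_kg": r.dose,
                "time_h": r.time_h,
                "tissue": r.tissue,
                "concentration_ug_b_g": r.concentration,
            }
            for r in records
        ]
    )


def summarize(
    records: Sequence[TissueBoronRecord],
    detection_floor: Optional[float] = None,
) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and n of tissue boron concentrations.

    Groups are (compound, route, time_h, tissue).  Single-animal groups get
    SD 0 and are flagged in ``single_animal``.  If ``detection_floor`` is
    given, the count of below-floor animals per group is reported.
    """
    if len(records) == 0:
        warnings.warn("no biodistribution records supplied; empty summary", stacklevel=2)
        return pd.DataFrame(
            columns=[*GROUP_KEYS, "mean", "sd", "n", "single_animal", "n_below_floor"]
        )
    frame = records_to_frame(records)
    rows = []
    for keys, group in frame.groupby(list(GROUP_KEYS), sort=True):
        values = group["concentration_ug_b_g"]
        n = len(values)
        row = dict(zip(GROUP_KEYS, keys))
        row["mean"] = float(values.mean())
        row["sd"] = float(values.std(ddof=1)) if n > 1 else 0.0
        row["n"] = n
        row["single_animal"] = n == 1
        if detection_floor is not None:
            row["n_below_floor"] = int((values < detection_floor).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def tumor_ratios(
    tumor_mean: float,
    brain_mean: float,
    blood_mean: float,
    round_to: Union[int, None] = 1,
) -> tuple[float, float]:
    """(tumor/brain, tumor/blood) concentration ratios from group means.

    A zero denominator yields NaN for that ratio (undefined-ratio sentinel)
    rather than raising.  ``round_to=None`` disables reporting rounding.
    """
    for name, value in (("tumor", tumor_mean), ("brain", brain_mean), ("blood", blood_mean)):
        if not math.isfinite(value) or value < 0:
            raise InvalidInputError(f"{name} mean must be finite and >= 0, got {value!r}")
    t_br = tumor_mean / brain_mean if brain_mean > 0 else math.nan
    t_bl = tumor_mean / blood_mean if blood_mean > 0 else math.nan
    if round_to is not None:
        t_br = round_half_up(t_br, round_to)
        t_bl = round_half_up(t_bl, round_to)
    return t_br, t_bl


def apply_detection_floor(
    records: Sequence[TissueBoronRecord], floor: float
) -> pd.DataFrame:
    """Flag (never zero out) concentrations below the detection floor.

    Returns the record table with an extra boolean ``below_detection`` column;
    the measured values are preserved so summaries remain computable.
    """
    if not math.isfinite(floor) or floor < 0:
        raise InvalidInputError(f"floor must be finite and >= 0, got {floor!r}")
    frame = records_to_frame(records)
    frame["below_detection"] = frame["concentration_ug_b_g"] < floor
    return frame
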