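"""Kaplan-Meier estimation, log-rank comparison and percent increased lifespan.

The estimators are implemented directly (product-limit and two-group
Mantel-Cox with the hypergeometric tie-corrected variance); the test suite
cross-checks them against an independent survival library.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedTestError
from .rounding import round_half_up

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "NOT_REACHED",
    "km_estimate",
    "km_from_arrays",
    "median_survival",
    "log_rank",
    "log_rank_arrays",
    "percent_ils",
    "survival_report",
]

#: Sentinel returned when a Kaplan-Meier curve never reaches 0.5.
NOT_REACHED = math.inf


@dataclass(frozen=True)
class SurvivalRecord:
    """One animal's follow-up time (days) and event indicator (1 = death)."""

    animal_id: str
    group: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time <= 0:
            raise InvalidInputError(f"time must be finite and > 0, got {self.time!r}")
        if self.event not in (0, 1):
            raise InvalidInputError(f"event must be 0 or 1, got {self.event!r}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve: S(t) at each distinct observed time, plus risk sets.

    ``times`` starts at 0 with survival 1.0; ``events``/``censored`` count the
    subjects leaving the risk set at each time.
    """

    times: np.ndarray
    survival_probabilities: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray

    @property
    def n(self) -> int:
        return int(self.at_risk[0]) if self.at_risk.size else 0

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())


def km_from_arrays(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate from raw time/event arrays."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise InvalidInputError("need at least one subject")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times)
    n_at_risk = times.size
    out_t, out_s, out_r, out_d, out_c = [0.0], [1.0], [n_at_risk], [0], [0]
    surv = 1.0
    for t in distinct:
        here = times == t
        d = int(events[here].sum())
        c = int(here.sum() - d)
        if d > 0:
            surv *= 1.0 - d / n_at_risk
        out_t.append(float(t))
        out_s.append(surv)
        out_r.append(n_at_risk)
        out_d.append(d)
        out_c.append(c)
        n_at_risk -= d + c
    return KMCurve(
        times=np.asarray(out_t),
        survival_probabilities=np.asarray(out_s),
        at_risk=np.asarray(out_r, dtype=int),
        events=np.asarray(out_d, dtype=int),
        censored=np.asarray(out_c, dtype=int),
    )


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier curve for one group of records."""
    if len(records) == 0:
        raise InvalidInputError("empty group")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    return km_from_arrays(times, events)


def median_survival(curve: KMCurve) -> float:
    """Median survival time from a Kaplan-Meier curve.

    With complete data (no censoring) this is the classical sample median of
    the death times — the midpoint of the two central order statistics for
    even n.  With censoring it is the smallest time at which the curve drops
    to 0.5 or below; :data:`NOT_REACHED` (inf) when the curve never does.
    """
    if curve.n_censored == 0 and curve.events.sum() > 0:
        deaths = np.repeat(curve.times, curve.events)
        return float(np.median(deaths))
    below = curve.survival_probabilities <= 0.5
    if not below.any():
        return NOT_REACHED
    return float(curve.times[int(np.argmax(below))])


def log_rank_arrays(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group Mantel-Cox log-rank test; returns (chi-square, p).

    Uses the hypergeometric variance with tie correction
    ``V_j = d_j (n1_j/n_j)(1 - n1_j/n_j)(n_j - d_j)/(n_j - 1)``.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise InvalidInputError("both groups must be nonempty")
    if events_a.sum() + events_b.sum() == 0:
        raise UndefinedTestError("no events in either group; log-rank undefined")
    event_times = np.unique(
        np.concatenate([times_a[events_a == 1], times_b[events_b == 1]])
    )
    observed_minus_expected = 0.0
    variance = 0.0
    for t in event_times:
        n1 = int((times_a >= t).sum())
        n2 = int((times_b >= t).sum())
        n = n1 + n2
        d1 = int(((times_a == t) & (events_a == 1)).sum())
        d2 = int(((times_b == t) & (events_b == 1)).sum())
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        observed_minus_expected += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0.0:
        return 0.0, 1.0
    chi_square = observed_minus_expected**2 / variance
    return float(chi_square), float(stats.chi2.sf(chi_square, df=1))


def log_rank(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Log-rank test between two groups of records."""
    return log_rank_arrays(
        np.asarray([r.time for r in group_a]),
        np.asarray([r.event for r in group_a]),
        np.asarray([r.time for r in group_b]),
        np.asarray([r.event for r in group_b]),
    )


def percent_ils(
    group_mst: float, control_mst: float, round_to: Union[int, None] = 1
) -> float:
    """Percent increased lifespan: 100 * (group MST / control MST - 1)."""
    if not math.isfinite(control_mst) or control_mst <= 0:
        raise InvalidInputError(f"control MST must be > 0, got {control_mst!r}")
    value = 100.0 * (group_mst / control_mst - 1.0)
    return round_half_up(value, round_to) if round_to is not None else value


def survival_report(
    records: Sequence[SurvivalRecord],
    control_group: str,
    holm: bool = False,
    round_to: Union[int, None] = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level survival summary plus a pairwise log-rank p-value matrix.

    Per group: n, mean +/- SD of follow-up times, Kaplan-Meier median, range
    and percent increased lifespan relative to the control group's median.
    ``holm`` optionally applies a Holm step-down correction to the pairwise
    p-values (off by default).
    """
    frame = pd.DataFrame(
        [{"group": r.group, "time": r.time, "event": r.event} for r in records]
    )
    if frame.empty:
        raise InvalidInputError("no survival records supplied")
    groups = list(dict.fromkeys(frame["group"]))  # preserve input order
    if control_group not in groups:
        raise InvalidInputError(f"control group {control_group!r} not present")
    by_group = {g: [r for r in records if r.group == g] for g in groups}
    control_mst = median_survival(km_estimate(by_group[control_group]))

    rows = []
    for g in groups:
        times = frame.loc[frame["group"] == g, "time"]
        mst = median_survival(km_estimate(by_group[g]))
        ils = (
            percent_ils(mst, control_mst, round_to=round_to)
            if math.isfinite(mst) and math.isfinite(control_mst)
            else math.nan
        )
        rows.append(
            {
                "group": g,
                "n": len(times),
                "mean": float(times.mean()),
                "sd": float(times.std(ddof=1)) if len(times) > 1 else 0.0,
                "median": mst,
                "range_min": float(times.min()),
                "range_max": float(times.max()),
                "pct_ils": ils,
            }
        )
    summary = pd.DataFrame(rows)

    p_matrix = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    pairs = list(itertools.combinations(groups, 2))
    p_values = []
    for a, b in pairs:
        _, p = log_rank(by_group[a], by_group[b])
        p_values.append(p)
    if holm and p_values:
        order = np.argsort(p_values)
        m = len(p_values)
        adjusted = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p_values[idx]))
            adjusted[idx] = running
        p_values = adjusted
    for (a, b), p in zip(pairs, p_values):
        p_matrix.loc[a, b] = p
        p_matrix.loc[b, a] = p
    return summary, p_matrix
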