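"""Linear-quadratic dose-response fitting and iso-effect RBE/CBE estimation.

The LQ model SF(D) = exp(-alpha*D - beta*D^2) is fitted by ordinary least
squares on -ln(SF) (variance-stabilizing under multiplicative survival
error), with alpha, beta constrained nonnegative via NNLS.  Iso-effect doses
are read off the fitted curve analytically, never by interpolating raw
points.

Boron weighting factor (CBE) definition
---------------------------------------
The CBE of a compound is extracted from an iso-effect comparison at a fixed
survival level (default SF = 0.1).  With t* the irradiation time at which the
compound-loaded cells reach the level, D_x the photon dose producing the same
level on the reference photon curve, and per-component beam doses accumulated
over t*:

    CBE = (D_x - RBE_N * D_N(t*) - RBE_H * D_H(t*) - D_gamma(t*)) / D_B(t*)

This subtraction-of-weighted-beam-terms form is the single authoritative
definition used throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.optimize import nnls

from .dosimetry import DoseComponents, WeightSet, total_physical_dose
from .errors import (
    DegenerateModelError,
    ExtrapolationWarning,
    InvalidInputError,
    NonPhysicalCBEWarning,
    UnderdeterminedError,
)

__all__ = [
    "DoseSFPoint",
    "LQParams",
    "IsoEffectResult",
    "CBEResult",
    "fit_lq",
    "sf_from_dose",
    "dose_at_sf",
    "beam_rbe",
    "compound_cbe",
]


@dataclass(frozen=True)
class DoseSFPoint:
    """One (dose, surviving fraction) observation."""

    dose: float
    sf: float
    condition_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.dose) or self.dose < 0:
            raise InvalidInputError(f"dose must be finite and >= 0, got {self.dose!r}")
        if not math.isfinite(self.sf) or not (0.0 < self.sf <= 1.0):
            raise InvalidInputError(f"sf must lie in (0, 1], got {self.sf!r}")


@dataclass
class LQParams:
    """Linear-quadratic parameters for one radiation quality.

    ``fit_covariance`` is the asymptotic covariance of (alpha, beta) from the
    least-squares fit (zeros for externally supplied parameters);
    ``at_boundary`` flags a fit that ended on the nonnegativity constraint.
    """

    alpha: float
    beta: float
    fit_covariance: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2), dtype=float)
    )
    residuals: Union[np.ndarray, None] = None
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidInputError(
                f"alpha and beta must be >= 0, got ({self.alpha!r}, {self.beta!r})"
            )
        self.fit_covariance = np.asarray(self.fit_covariance, dtype=float)
        if self.fit_covariance.shape != (2, 2):
            raise InvalidInputError("fit_covariance must be a 2x2 matrix")


@dataclass(frozen=True)
class IsoEffectResult:
    """Iso-effect dose comparison at a fixed survival level."""

    sf_level: float
    reference_dose: float
    comparison_dose: float
    rbe: float


@dataclass(frozen=True)
class CBEResult:
    """Boron weighting factor extracted from one compound exposure series."""

    cbe: float
    sf_level: float
    photon_iso_dose: float
    iso_effect_time: float
    components: DoseComponents
    physical_dose: float

    def __float__(self) -> float:  # allow use directly as a number
        return self.cbe


def _as_arrays(points: Sequence[DoseSFPoint]) -> tuple[np.ndarray, np.ndarray]:
    doses = np.asarray([p.dose for p in points], dtype=float)
    sfs = np.asarray([p.sf for p in points], dtype=float)
    return doses, sfs


def fit_lq(
    points: Sequence[DoseSFPoint],
    weights: Union[Sequence[float], None] = None,
) -> LQParams:
    """Least-squares LQ fit of -ln(SF) = alpha*D + beta*D^2 with alpha, beta >= 0.

    Parameters
    ----------
    points : sequence of DoseSFPoint
        At least three distinct doses, all with sf > 0 (enforced by the type).
    weights : optional sequence of float
        Per-point weights applied to the squared residuals (e.g. inverse
        variances); default is ordinary least squares.

    Returns
    -------
    LQParams with the fitted covariance and residual vector attached.
    """
    if len(points) == 0:
        raise UnderdeterminedError("no points supplied")
    doses, sfs = _as_arrays(points)
    if np.unique(doses).size < 3:
        raise UnderdeterminedError(
            f"need >= 3 distinct doses to identify (alpha, beta); got {np.unique(doses).size}"
        )
    y = -np.log(sfs)
    design = np.column_stack([doses, doses**2])
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise InvalidInputError("weights must be finite, nonnegative, one per point")
        sw = np.sqrt(w)
        design = design * sw[:, None]
        y = y * sw
    coef, _ = nnls(design, y)
    residuals = y - design @ coef
    dof = y.size - 2
    sigma2 = float(residuals @ residuals) / dof if dof > 0 else 0.0
    gram = design.T @ design
    covariance = sigma2 * np.linalg.pinv(gram)
    return LQParams(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        fit_covariance=covariance,
        residuals=residuals,
        at_boundary=bool(coef[0] == 0.0 or coef[1] == 0.0),
    )


def sf_from_dose(lq: LQParams, dose: float) -> float:
    """SF(D) = exp(-alpha*D - beta*D^2), in (0, 1] for D >= 0."""
    if not math.isfinite(dose) or dose < 0:
        raise InvalidInputError(f"dose must be finite and >= 0, got {dose!r}")
    return math.exp(-lq.alpha * dose - lq.beta * dose**2)


def dose_at_sf(lq: LQParams, sf_level: float) -> float:
    """Unique nonnegative dose with SF(D) = sf_level (LQ inversion).

    Solves alpha*D + beta*D^2 = -ln(sf_level); the beta = 0 case is handled
    analytically.  Raises DegenerateModelError when alpha = beta = 0.
    """
    if not math.isfinite(sf_level) or not (0.0 < sf_level <= 1.0):
        raise InvalidInputError(f"sf_level must lie in (0, 1], got {sf_level!r}")
    if lq.alpha == 0.0 and lq.beta == 0.0:
        raise DegenerateModelError("alpha = beta = 0: survival does not depend on dose")
    target = -math.log(sf_level)
    # positive root of beta*D^2 + alpha*D - target = 0 in the cancellation-free
    # form 2*target / (alpha + sqrt(alpha^2 + 4*beta*target)); reduces to
    # target/alpha as beta -> 0 and to sqrt(target/beta) as alpha -> 0
    if target == 0.0:
        return 0.0
    return 2.0 * target / (lq.alpha + math.sqrt(lq.alpha**2 + 4.0 * lq.beta * target))


def _check_span(sfs: np.ndarray, sf_level: float, label: str) -> None:
    if not (sfs.min() <= sf_level <= sfs.max()):
        warnings.warn(
            f"{label}: sf_level {sf_level} lies outside the observed SF range "
            f"[{sfs.min():.4g}, {sfs.max():.4g}]; iso-effect value is an extrapolation",
            ExtrapolationWarning,
            stacklevel=3,
        )


def beam_rbe(
    photon_lq: LQParams,
    beam_points: Sequence[DoseSFPoint],
    sf_level: float = 0.1,
) -> IsoEffectResult:
    """Beam RBE at an iso-effect survival level.

    The beam response is fitted with the same LQ form; RBE is the photon dose
    at ``sf_level`` divided by the fitted beam physical dose at ``sf_level``.
    A warning is emitted when ``sf_level`` is outside the observed beam SF
    range (extrapolation).
    """
    beam_lq = fit_lq(beam_points)
    _, sfs = _as_arrays(beam_points)
    _check_span(sfs, sf_level, "beam_rbe")
    reference = dose_at_sf(photon_lq, sf_level)
    comparison = dose_at_sf(beam_lq, sf_level)
    return IsoEffectResult(
        sf_level=sf_level,
        reference_dose=reference,
        comparison_dose=comparison,
        rbe=reference / comparison,
    )


def compound_cbe(
    photon_lq: LQParams,
    compound_points: Sequence[DoseSFPoint],
    beam_rates: DoseComponents,
    boron_dose_rate: float,
    weights: WeightSet,
    sf_level: float = 0.1,
) -> CBEResult:
    """Extract the compound's boron weighting factor at an iso-effect level.

    Parameters
    ----------
    photon_lq : LQParams
        Reference photon survival curve.
    compound_points : sequence of DoseSFPoint
        Survival of the compound-loaded cells; here the ``dose`` field carries
        the elapsed irradiation time in minutes (the abscissa on which the
        exposure is controlled; all dose components scale linearly with it).
    beam_rates : DoseComponents
        Boron-free beam component dose rates in Gy per minute (``d_boron``
        must be 0 — the boron channel is supplied separately).
    boron_dose_rate : float
        Boron physical dose rate for this compound/loading, Gy per minute.
    weights : WeightSet
        Supplies RBE_N and RBE_H (its ``cbe`` field is ignored here).
    sf_level : float
        Iso-effect survival level, default 0.1.

    Notes
    -----
    A nonpositive numerator (boron effect indistinguishable from zero) is
    reported as-is with a :class:`NonPhysicalCBEWarning` diagnostic rather
    than raised, so that batch reports can flag rather than abort.
    """
    if not (math.isfinite(boron_dose_rate) and boron_dose_rate > 0):
        raise InvalidInputError(f"boron_dose_rate must be > 0, got {boron_dose_rate!r}")
    if beam_rates.d_boron != 0.0:
        raise InvalidInputError(
            "beam_rates.d_boron must be 0; boron enters through boron_dose_rate"
        )
    time_lq = fit_lq(compound_points)  # -ln(SF) quadratic in time, rates constant
    _, sfs = _as_arrays(compound_points)
    _check_span(sfs, sf_level, "compound_cbe")
    t_star = dose_at_sf(time_lq, sf_level)
    components = DoseComponents(
        d_boron=boron_dose_rate * t_star,
        d_nitrogen=beam_rates.d_nitrogen * t_star,
        d_hydrogen=beam_rates.d_hydrogen * t_star,
        d_gamma=beam_rates.d_gamma * t_star,
    )
    photon_iso = dose_at_sf(photon_lq, sf_level)
    numerator = (
        photon_iso
        - weights.rbe_n * components.d_nitrogen
        - weights.rbe_h * components.d_hydrogen
        - components.d_gamma
    )
    if numerator <= 0:
        warnings.warn(
            "non-physical CBE: weighted beam terms meet or exceed the photon "
            "iso-effect dose (boron component indistinguishable from zero)",
            NonPhysicalCBEWarning,
            stacklevel=2,
        )
    return CBEResult(
        cbe=numerator / components.d_boron,
        sf_level=sf_level,
        photon_iso_dose=photon_iso,
        iso_effect_time=t_star,
        components=components,
        physical_dose=total_physical_dose(components),
    )
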