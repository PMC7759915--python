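import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnctkit.dosimetry import DoseComponents, WeightSet
from bnctkit.errors import (
    DegenerateModelError,
    ExtrapolationWarning,
    InvalidInputError,
    NonPhysicalCBEWarning,
    UnderdeterminedError,
)
from bnctkit.radiobiology import (
    DoseSFPoint,
    LQParams,
    beam_rbe,
    compound_cbe,
    dose_at_sf,
    fit_lq,
    sf_from_dose,
)


def lq_points(alpha, beta, doses):
    return [
        DoseSFPoint(dose=d, sf=math.exp(-alpha * d - beta * d**2)) for d in doses
    ]


# ---------------------------------------------------------------------------
# fit_lq


def test_fit_exact_exponential():
    lq = fit_lq(lq_points(0.5, 0.0, [1, 2, 3, 4]))
    assert lq.alpha == pytest.approx(0.5, abs=1e-9)
    assert lq.beta == pytest.approx(0.0, abs=1e-9)


def test_fit_noiseless_identifiability():
    lq = fit_lq(lq_points(0.2, 0.02, range(1, 9)))
    assert lq.alpha == pytest.approx(0.2, abs=1e-6)
    assert lq.beta == pytest.approx(0.02, abs=1e-6)


def test_fit_noisy_recovery_within_ten_percent():
    # multiplicative SF noise, n = 30, median error over 200 seeds
    alpha, beta = 0.2, 0.02
    doses = np.tile(np.linspace(1, 12, 10), 3)
    err_a, err_b = [], []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        sf = np.minimum(
            np.exp(-alpha * doses - beta * doses**2) * np.exp(rng.normal(0, 0.2, doses.size)),
            1.0,
        )
        lq = fit_lq([DoseSFPoint(float(d), float(s)) for d, s in zip(doses, sf)])
        err_a.append(abs(lq.alpha - alpha) / alpha)
        err_b.append(abs(lq.beta - beta) / beta)
    assert np.median(err_a) <= 0.10
    assert np.median(err_b) <= 0.10


def test_fit_requires_three_distinct_doses():
    with pytest.raises(UnderdeterminedError):
        fit_lq(lq_points(0.2, 0.02, [1, 1, 2]))


def test_fit_rejects_nonpositive_sf():
    with pytest.raises(InvalidInputError):
        DoseSFPoint(dose=1.0, sf=0.0)


def test_fit_nonnegativity_constraint_flagged():
    # data that wants beta < 0: concave -ln(SF)
    doses = np.array([1.0, 2.0, 4.0, 8.0])
    y = np.sqrt(doses)  # sublinear
    points = [DoseSFPoint(float(d), float(math.exp(-v))) for d, v in zip(doses, y)]
    lq = fit_lq(points)
    assert lq.beta == 0.0
    assert lq.at_boundary


def _grid_search(doses, y, n_zoom=5, n_grid=121):
    """Independent oracle: refining grid search over the same OLS loss."""
    a, b = np.linalg.lstsq(np.column_stack([doses, doses**2]), y, rcond=None)[0]
    lo_a, hi_a = 0.0, max(2.5 * abs(a), 1.0)
    lo_b, hi_b = 0.0, max(2.5 * abs(b), 0.3)
    best = (0.0, 0.0)
    for _ in range(n_zoom):
        grid_a = np.linspace(lo_a, hi_a, n_grid)
        grid_b = np.linspace(lo_b, hi_b, n_grid)
        resid = (
            y[None, None, :]
            - grid_a[:, None, None] * doses[None, None, :]
            - grid_b[None, :, None] * doses[None, None, :] ** 2
        )
        loss = (resid**2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(loss), loss.shape)
        best = (grid_a[i], grid_b[j])
        da = (hi_a - lo_a) / (n_grid - 1)
        db = (hi_b - lo_b) / (n_grid - 1)
        lo_a, hi_a = max(best[0] - 2 * da, 0.0), best[0] + 2 * da
        lo_b, hi_b = max(best[1] - 2 * db, 0.0), best[1] + 2 * db
    return best


def test_fit_agrees_with_grid_search_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(4, 13)
        alpha = rng.uniform(0.05, 0.5)
        beta = rng.uniform(0.005, 0.08)
        doses = np.sort(rng.uniform(0.5, 8.0, n))
        sf = np.minimum(
            np.exp(-alpha * doses - beta * doses**2) * np.exp(rng.normal(0, 0.1, n)), 1.0
        )
        lq = fit_lq([DoseSFPoint(float(d), float(s)) for d, s in zip(doses, sf)])
        a_grid, b_grid = _grid_search(doses, -np.log(sf))
        assert lq.alpha == pytest.approx(a_grid, abs=1e-4)
        assert lq.beta == pytest.approx(b_grid, abs=1e-4)


# ---------------------------------------------------------------------------
# sf_from_dose / dose_at_sf


def test_sf_zero_dose():
    assert sf_from_dose(LQParams(0.3, 0.03), 0.0) == 1.0


def test_sf_analytic_log10():
    assert sf_from_dose(LQParams(math.log(10), 0.0), 1.0) == pytest.approx(0.1)


def test_sf_hand_arithmetic():
    assert sf_from_dose(LQParams(0.3, 0.03), 5.0) == pytest.approx(math.exp(-2.25))


def test_sf_negative_dose_rejected():
    with pytest.raises(InvalidInputError):
        sf_from_dose(LQParams(0.3, 0.03), -1.0)


def test_dose_at_sf_identity_level():
    assert dose_at_sf(LQParams(0.3, 0.03), 1.0) == pytest.approx(0.0)


def test_dose_at_sf_linear_analytic():
    assert dose_at_sf(LQParams(0.5, 0.0), 0.1) == pytest.approx(math.log(10) / 0.5)


def test_dose_at_sf_degenerate_model():
    with pytest.raises(DegenerateModelError):
        dose_at_sf(LQParams(0.0, 0.0), 0.5)


def test_dose_at_sf_invalid_level():
    with pytest.raises(InvalidInputError):
        dose_at_sf(LQParams(0.3, 0.03), 0.0)


nonneg_param = st.one_of(st.just(0.0), st.floats(1e-4, 2.0))


@given(alpha=nonneg_param, beta=nonneg_param, sf_level=st.floats(1e-6, 1.0))
@settings(max_examples=200)
def test_inversion_round_trip(alpha, beta, sf_level):
    if alpha == 0.0 and beta == 0.0:
        return
    lq = LQParams(alpha, beta)
    dose = dose_at_sf(lq, sf_level)
    assert sf_from_dose(lq, dose) == pytest.approx(sf_level, abs=1e-10)


@given(
    alpha=st.floats(0.01, 1.0),
    beta=st.floats(0.0, 0.2),
    d1=st.floats(0.0, 20.0),
    d2=st.floats(0.0, 20.0),
)
@settings(max_examples=200)
def test_monotonicity(alpha, beta, d1, d2):
    lq = LQParams(alpha, beta)
    lo, hi = sorted([d1, d2])
    if hi - lo > 1e-6:
        assert sf_from_dose(lq, hi) < sf_from_dose(lq, lo)


# ---------------------------------------------------------------------------
# beam_rbe


def test_beam_rbe_self_comparison():
    photon = LQParams(0.2, 0.02)
    points = lq_points(0.2, 0.02, [1, 3, 5, 7, 9, 12])
    result = beam_rbe(photon, points, sf_level=0.1)
    assert result.rbe == pytest.approx(1.0, abs=1e-8)


def test_beam_rbe_analytic_roots():
    photon = LQParams(0.2, 0.02)
    beam_points = lq_points(0.6, 0.02, [0.5, 1, 2, 3, 4])
    result = beam_rbe(photon, beam_points, sf_level=0.1)
    expected = dose_at_sf(photon, 0.1) / dose_at_sf(LQParams(0.6, 0.02), 0.1)
    assert result.rbe == pytest.approx(expected, rel=1e-8)


def test_beam_rbe_uniform_scaling_is_two():
    # SF_beam(D) = SF_photon(2D): alpha doubles, beta quadruples
    photon = LQParams(0.2, 0.02)
    beam_points = lq_points(0.4, 0.08, [0.5, 1, 2, 3, 4, 5])
    result = beam_rbe(photon, beam_points, sf_level=0.1)
    assert result.rbe == pytest.approx(2.0, rel=1e-8)


def test_beam_rbe_extrapolation_warns():
    photon = LQParams(0.2, 0.02)
    shallow = lq_points(0.2, 0.02, [0.1, 0.2, 0.3])  # SF stays near 1
    with pytest.warns(ExtrapolationWarning):
        beam_rbe(photon, shallow, sf_level=0.1)


# ---------------------------------------------------------------------------
# compound_cbe


def _time_points(rate_eq, photon, minutes=(10, 30, 60)):
    return [
        DoseSFPoint(dose=t, sf=sf_from_dose(photon, rate_eq * t)) for t in minutes
    ]


def test_cbe_photon_equivalent_boron_is_one():
    # boron behaving exactly like photon dose, all weights 1 -> CBE 1
    photon = LQParams(0.3, 0.03)
    weights = WeightSet(cbe=1.0, rbe_n=1.0, rbe_h=1.0, cbe_brain=1.0)
    beam_rates = DoseComponents(0.0, 0.005, 0.005, 0.02)  # Gy/min
    boron_rate = 0.1
    total_rate = 0.1 + 0.005 + 0.005 + 0.02
    points = _time_points(total_rate, photon)
    result = compound_cbe(photon, points, beam_rates, boron_rate, weights)
    assert result.cbe == pytest.approx(1.0, rel=1e-8)


def test_cbe_doubling_boron_rate_halves_cbe():
    photon = LQParams(0.3, 0.03)
    weights = WeightSet(cbe=1.0)
    beam_rates = DoseComponents(0.0, 0.002, 0.002, 0.01)
    points = _time_points(0.12, photon)
    one = compound_cbe(photon, points, beam_rates, 0.05, weights)
    two = compound_cbe(photon, points, beam_rates, 0.10, weights)
    assert two.cbe == pytest.approx(one.cbe / 2.0, rel=1e-10)


def test_cbe_time_rescaling_invariance():
    photon = LQParams(0.3, 0.03)
    weights = WeightSet(cbe=2.0)
    beam_rates = DoseComponents(0.0, 0.002, 0.002, 0.01)
    points = _time_points(0.12, photon)
    base = compound_cbe(photon, points, beam_rates, 0.05, weights)
    # double every rate, halve every time
    points_fast = [DoseSFPoint(p.dose / 2.0, p.sf) for p in points]
    fast = compound_cbe(
        photon, points_fast, beam_rates.scaled(2.0), 0.10, weights
    )
    assert fast.cbe == pytest.approx(base.cbe, rel=1e-9)


def test_cbe_nonphysical_numerator_warns():
    photon = LQParams(0.3, 0.0)
    weights = WeightSet(cbe=1.0, rbe_n=3.0, rbe_h=3.0)
    # overwhelming weighted beam terms at the iso-effect time
    beam_rates = DoseComponents(0.0, 0.5, 0.5, 0.5)
    points = _time_points(0.2, photon)
    with pytest.warns(NonPhysicalCBEWarning):
        result = compound_cbe(photon, points, beam_rates, 0.001, weights)
    assert result.cbe <= 0


def test_cbe_rejects_boron_in_beam_rates():
    photon = LQParams(0.3, 0.03)
    with pytest.raises(InvalidInputError):
        compound_cbe(
            photon,
            _time_points(0.1, photon),
            DoseComponents(0.01, 0.0, 0.0, 0.01),
            0.05,
            WeightSet(cbe=1.0),
        )
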