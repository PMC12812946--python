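"""Spline basis, likelihood fitting, Weibull equivalence and model selection."""

import math

import numpy as np
import pytest
from lifelines import WeibullFitter

from psmcea import (
    FitBundle,
    default_trial_design,
    fit_candidates,
    fit_rp,
    generate_ipd,
    select_model,
    weibull_fit_from_params,
)
from psmcea.km_reconstruct import PseudoIPD
from psmcea.survival_fit import RPSplineFit, spline_basis, spline_basis_deriv


def test_basis_reduces_to_linear_without_interior_knots():
    b = spline_basis([0.0, 1.0, 2.5], np.array([0.0, 3.0]))
    assert np.allclose(b, [[1, 0], [1, 1], [1, 2.5]])


def test_basis_zero_at_lower_boundary_and_linear_beyond_upper():
    knots = np.array([0.0, 0.7, 1.3, 2.0])
    b = spline_basis(0.0, knots)
    assert np.allclose(b[0, 2:], 0.0)  # all plus-functions vanish at k_min
    # natural-spline linearity beyond k_max: second finite difference ~ 0
    xs = np.array([2.5, 2.6, 2.7])
    vals = spline_basis(xs, knots)[:, 2:]
    second_diff = vals[2] - 2 * vals[1] + vals[0]
    assert np.max(np.abs(second_diff)) < 1e-9
    # and curvature inside the knot span is non-trivial
    xs_in = np.array([0.9, 1.0, 1.1])
    vals_in = spline_basis(xs_in, knots)[:, 2:]
    assert np.max(np.abs(vals_in[2] - 2 * vals_in[1] + vals_in[0])) > 1e-6


def test_basis_rejects_duplicate_knots():
    with pytest.raises(ValueError):
        spline_basis(1.0, np.array([0.0, 1.0, 1.0, 2.0]))


def _sim_weibull_ipd(shape, scale, n, seed, censor=None):
    rng = np.random.default_rng(seed)
    raw = scale * rng.weibull(shape, size=n)
    if censor is None:
        return PseudoIPD(time=raw, event=np.ones(n, dtype=int))
    t = np.minimum(raw, censor)
    return PseudoIPD(time=t, event=(raw <= censor).astype(int))


@pytest.mark.parametrize("seed", range(20))
def test_zero_knot_fit_equals_weibull_mle(seed):
    """The 0-interior-knot fit on the log-cumulative-hazard scale IS a
    Weibull fit: log likelihood agrees with an independent Weibull MLE
    within optimizer tolerance."""
    ipd = _sim_weibull_ipd(1.3, 12.0, 300, seed, censor=20.0)
    fit = fit_rp(ipd, 0)
    wf = WeibullFitter().fit(ipd.time, ipd.event)
    assert fit.loglik == pytest.approx(wf.log_likelihood_, abs=1e-4)
    assert fit.gamma[1] == pytest.approx(wf.rho_, rel=1e-3)
    assert math.exp(-fit.gamma[0] / fit.gamma[1]) == pytest.approx(wf.lambda_, rel=1e-3)


def test_exponential_recovery_zero_knots():
    """Shape-1 data: fitted survival within 0.02 of the true exponential and
    the log-time coefficient close to 1."""
    ipd = _sim_weibull_ipd(1.0, 10.0, 2000, 7)
    fit = fit_rp(ipd, 0)
    assert fit.gamma[1] == pytest.approx(1.0, abs=0.05)
    t = np.linspace(0.1, 30, 50)
    assert np.max(np.abs(fit.survival(t) - np.exp(-t / 10.0))) < 0.02


def test_weibull_shape_recovery_at_trial_calibration():
    ipd = _sim_weibull_ipd(1.1717, 20.51, 2000, 21, censor=21.4)
    fit = fit_rp(ipd, 0)
    assert fit.gamma[1] == pytest.approx(1.1717, abs=0.1)


def test_more_knots_never_lower_loglik():
    ipd = _sim_weibull_ipd(1.3, 12.0, 500, 3, censor=18.0)
    ll0 = fit_rp(ipd, 0).loglik
    ll3 = fit_rp(ipd, 3).loglik
    assert ll3 >= ll0 - 1e-6


def test_aic_bic_consistency_and_no_events_error():
    ipd = _sim_weibull_ipd(1.3, 12.0, 400, 5, censor=18.0)
    fit = fit_rp(ipd, 1)
    k = fit.n_params
    assert fit.aic - fit.bic == pytest.approx(2 * k - k * math.log(fit.n_events), abs=1e-9)
    with pytest.raises(ValueError):
        fit_rp(PseudoIPD(time=[1.0, 2.0], event=[0, 0]), 0)


def _dummy_fit(label, aic, bic, n_params):
    return RPSplineFit(
        knots=np.concatenate([[0.0], np.linspace(0.2, 0.8, n_params - 2), [1.0]]),
        gamma=np.ones(n_params),
        loglik=0.0,
        aic=aic,
        bic=bic,
        n_events=10,
        n_obs=10,
        label=label,
    )


def test_select_model_argmin_and_ties():
    b = FitBundle()
    b.add(_dummy_fit("a", 100.0, 101.0, 2))
    assert select_model(b, "aic").label == "a"  # single candidate
    b.add(_dummy_fit("b", 98.0, 99.0, 3))
    b.add(_dummy_fit("c", 103.0, 104.0, 2))
    assert select_model(b, "aic").label == "b"
    # tie on AIC -> fewer parameters wins
    b2 = FitBundle()
    b2.add(_dummy_fit("rich", 98.0, 100.0, 4))
    b2.add(_dummy_fit("lean", 98.0, 99.0, 2))
    assert select_model(b2, "aic").label == "lean"
    with pytest.raises(ValueError):
        select_model(FitBundle(), "aic")
    with pytest.raises(ValueError):
        select_model(b, "dic")


def test_bic_prefers_parsimonious_truth():
    """When the generating model is Weibull, BIC picks the 0-knot reduction
    in a large majority of replicates."""
    wins = 0
    n_rep = 20
    for seed in range(n_rep):
        ipd = _sim_weibull_ipd(1.17, 20.5, 300, 100 + seed, censor=21.4)
        bundle = fit_candidates(ipd, knot_counts=(0, 1, 2, 3), criterion="bic")
        wins += bundle.selected == "rp0"
    assert wins / n_rep >= 0.8


def test_exact_weibull_wrapper_identities():
    """gamma = (-k ln l, k) reproduces S(t) = exp(-(t/l)^k) exactly, S(0)=1,
    survival is non-increasing, and the analytic hazard matches a finite
    difference of the cumulative hazard."""
    k, lam = 1.7373, 41.99
    fit = weibull_fit_from_params(k, lam)
    t = np.linspace(0.5, 120, 10)
    assert np.allclose(fit.survival(t), np.exp(-((t / lam) ** k)), rtol=1e-12)
    assert fit.survival(0.0)[0] == 1.0
    grid = np.linspace(0.0, 200, 400)
    s = fit.survival(grid)
    assert np.all(np.diff(s) <= 1e-15)
    eps = 1e-6
    fd = (fit.cumhaz(t + eps) - fit.cumhaz(t - eps)) / (2 * eps)
    assert np.allclose(fit.hazard(t), fd, rtol=1e-5)
    with pytest.raises(ValueError):
        fit.hazard(0.0)
    with pytest.raises(ValueError):
        fit.survival(-1.0)


def test_fit_roundtrips_through_json(tmp_path):
    ipd = _sim_weibull_ipd(1.3, 12.0, 300, 2, censor=18.0)
    fit = fit_rp(ipd, 1)
    clone = RPSplineFit.from_json(fit.to_json())
    t = np.linspace(0.5, 60, 20)
    assert np.allclose(clone.survival(t), fit.survival(t), rtol=1e-12)
    assert clone.aic == fit.aic
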