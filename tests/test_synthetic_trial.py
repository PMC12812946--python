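"""Calibration of the common-shape Weibull pair and trial generation."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.optimize import brentq

from psmcea import (
    calibrate_weibull_pair,
    default_trial_design,
    generate_ipd,
    km_curve,
)
from psmcea.km_reconstruct import PseudoIPD
from psmcea.synthetic_trial import ArmSpec, TrialDesign, km_median

from conftest import product_limit_oracle


@pytest.mark.parametrize(
    "m_trt, m_ctl, hr",
    [(15.0, 7.3, 0.43), (34.0, 27.0, 0.67)],
)
def test_calibration_satisfies_medians_and_hr(m_trt, m_ctl, hr):
    """Shape solves (m_ctl/m_trt)^k = hr; scales invert to the medians; the
    hazard ratio is constant and equal to the target at arbitrary times."""
    shape, sc_trt, sc_ctl = calibrate_weibull_pair(m_trt, m_ctl, hr)
    # independent scalar root check for the shape
    k_root = brentq(lambda k: (m_ctl / m_trt) ** k - hr, 1e-3, 50)
    assert shape == pytest.approx(k_root, abs=1e-9)
    # medians by numeric inversion of each survival function
    for sc, med in [(sc_trt, m_trt), (sc_ctl, m_ctl)]:
        t_med = brentq(lambda t: math.exp(-((t / sc) ** shape)) - 0.5, 1e-6, 500)
        assert t_med == pytest.approx(med, abs=1e-9)
    # numeric hazard ratio at 10 time points
    for t in np.linspace(0.5, 40, 10):
        h = lambda s: (shape / s) * (t / s) ** (shape - 1)
        assert h(sc_trt) / h(sc_ctl) == pytest.approx(hr, rel=1e-9)


def test_calibration_shape_values():
    assert calibrate_weibull_pair(15.0, 7.3, 0.43)[0] == pytest.approx(1.1717, abs=5e-4)
    assert calibrate_weibull_pair(34.0, 27.0, 0.67)[0] == pytest.approx(1.7373, abs=5e-4)


def test_calibration_identical_arms_and_errors():
    shape, s1, s2 = calibrate_weibull_pair(10.0, 10.0, 1.0)
    assert shape == 1.0 and s1 == s2
    with pytest.raises(ValueError):
        calibrate_weibull_pair(15.0, 7.3, 1.0)  # hr=1 with distinct medians
    with pytest.raises(ValueError):
        calibrate_weibull_pair(10.0, 10.0, 0.5)  # equal medians, hr<1
    with pytest.raises(ValueError):
        calibrate_weibull_pair(-1.0, 7.3, 0.43)
    with pytest.raises(ValueError):
        calibrate_weibull_pair(7.3, 15.0, 0.43)  # benefit arm must have longer median


def test_armspec_rejects_inconsistent_scale():
    with pytest.raises(ValueError):
        ArmSpec("bad", 10, median=15.0, shape=1.2, scale=10.0)
    with pytest.raises(ValueError):
        ArmSpec("tiny", 1, median=15.0, shape=1.0, scale=15.0 / math.log(2))


def test_design_requires_shared_shape():
    a = ArmSpec("t", 10, 15.0, 1.0, 15.0 / math.log(2))
    b = ArmSpec("c", 10, 7.3, 1.2, 7.3 / math.log(2) ** (1 / 1.2))
    with pytest.raises(ValueError):
        TrialDesign("pfs", a, b, 0.43, 21.4)


def test_generation_deterministic_and_censored(pfs_ipds):
    design, ipds = pfs_ipds
    again = generate_ipd(design)
    for arm in ("treatment", "control"):
        assert np.array_equal(ipds[arm].time, again[arm].time)
        assert np.array_equal(ipds[arm].event, again[arm].event)
        assert ipds[arm].time.max() <= design.censor_time + 1e-12
        # censored exactly the records hitting the administrative cut-off
        at_cap = ipds[arm].time == design.censor_time
        assert np.all(ipds[arm].event[~at_cap] == 1)
        assert np.all(ipds[arm].event[at_cap] == 0)


def test_degenerate_censoring_all_censored():
    design = default_trial_design("pfs", n_per_arm=50, seed=1)
    tiny = TrialDesign(
        design.endpoint, design.treatment, design.control, design.target_hr,
        censor_time=1e-9, seed=1,
    )
    ipds = generate_ipd(tiny)
    for ipd in ipds.values():
        assert np.all(ipd.event == 0)
        assert np.all(ipd.time <= 1e-9)


def test_km_medians_and_cox_hr_recover_design(pfs_ipds):
    """At n=2000/arm the generated trial reproduces the design medians
    (±0.5 months) and the proportional-hazards HR (±0.05)."""
    design, ipds = pfs_ipds
    assert km_median(ipds["treatment"]) == pytest.approx(15.0, abs=0.5)
    assert km_median(ipds["control"]) == pytest.approx(7.3, abs=0.5)
    df = pd.concat(
        [ipds[a].to_frame().assign(trt=int(a == "treatment")) for a in ipds]
    )[["time", "event", "trt"]]
    cph = CoxPHFitter().fit(df, "time", "event")
    assert float(np.exp(cph.params_["trt"])) == pytest.approx(0.43, abs=0.05)


def test_km_curve_matches_hand_oracle():
    """Product-limit coordinates agree exactly with a hand-rolled oracle on
    small inputs, including the textbook two-patient case."""
    ipd = PseudoIPD(time=[1.0, 2.0], event=[1, 1])
    curve = km_curve(ipd, risk_times=[0.0, 1.5])
    assert curve.coords[0].tolist() == [0.0, 1.0]
    assert curve.coords[1].tolist() == [1.0, 0.5]
    assert curve.coords[2].tolist() == [2.0, 0.0]
    assert curve.risk_table[:, 1].tolist() == [2, 1]

    rng = np.random.default_rng(5)
    t = rng.exponential(10, size=10).round(2)
    e = rng.integers(0, 2, size=10)
    e[0] = 1
    curve = km_curve(PseudoIPD(time=t, event=e), risk_times=[0.0, 5.0, 10.0])
    ot, os_ = product_limit_oracle(t, e)
    got = {round(a, 9): b for a, b in curve.coords}
    for tt, ss in zip(ot, os_):
        assert got[round(tt, 9)] == pytest.approx(ss, abs=1e-12)


def test_km_curve_all_censored_flat():
    ipd = PseudoIPD(time=[1.0, 2.0, 3.0], event=[0, 0, 0])
    curve = km_curve(ipd, risk_times=[0.0])
    assert np.all(curve.coords[:, 1] == 1.0)


def test_km_curve_close_to_true_survival(pfs_ipds):
    """Large-n curve within 0.02 sup-norm of the generating Weibull."""
    design, ipds = pfs_ipds
    for arm_spec in (design.treatment, design.control):
        curve = km_curve(ipds[arm_spec.name], risk_times=[0.0])
        t = curve.coords[:-1, 0]  # last point is the follow-up cap marker
        true_s = arm_spec.survival(t)
        assert np.max(np.abs(curve.coords[:-1, 1] - true_s)) < 0.02


def test_km_curve_rejects_empty():
    with pytest.raises(ValueError):
        km_curve(PseudoIPD(time=[], event=[]), risk_times=[0.0])
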