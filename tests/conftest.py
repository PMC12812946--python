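import numpy as np
import pytest

from psmcea import build_model, default_trial_design, generate_ipd


@pytest.fixture(scope="session")
def pfs_ipds():
    """Calibrated PFS trial, n=2000/arm, fixed seed."""
    design = default_trial_design("pfs", n_per_arm=2000, seed=42)
    return design, generate_ipd(design)


@pytest.fixture(scope="session")
def base_model():
    """Deterministic assembled model on the calibrated Weibull pair."""
    return build_model()


def product_limit_oracle(time, event):
    """Hand-rolled Kaplan-Meier product-limit estimator.

    Returns (event_times, survival) at each distinct event time —
    an independent cross-check for the packaged curve builder.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    s = 1.0
    out_t, out_s = [], []
    for t in np.unique(time[event == 1]):
        n_at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
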