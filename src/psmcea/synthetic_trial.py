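"""Synthetic two-arm trial generator with a calibrated Weibull survival structure.

The generator stands in for digitized trial data: a pair of Weibull
distributions sharing a common shape parameter reproduces, simultaneously
and exactly, the two arm medians and the constant hazard ratio a phase-III
readout prints.  Administrative censoring truncates follow-up the way a
data cut-off does.  Downstream stages (digitization, pseudo-IPD
reconstruction, spline fitting, the economic model) consume only the
marginal curves, so progression-free and overall survival are generated as
independent endpoint-level datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from psmcea.km_reconstruct import DigitizedCurve, PseudoIPD

__all__ = [
    "ArmSpec",
    "TrialDesign",
    "calibrate_weibull_pair",
    "default_trial_design",
    "generate_ipd",
    "km_curve",
    "km_median",
]


@dataclass(frozen=True)
class ArmSpec:
    """One arm of one endpoint: a Weibull event-time distribution.

    Parameters
    ----------
    name : arm label (e.g. ``"treatment"``).
    n : number of patients; at least 2.
    median : target median event time in months.
    shape : Weibull shape ``k``.
    scale : Weibull scale ``lambda`` in months; survival is
        ``S(t) = exp(-(t / scale)**shape)``.
    """

    name: str
    n: int
    median: float
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("arm size n must be >= 2")
        if min(self.median, self.shape, self.scale) <= 0:
            raise ValueError("median, shape and scale must be positive")
        # scale derived from median must put the survival median where stated
        s_at_median = math.exp(-((self.median / self.scale) ** self.shape))
        if abs(s_at_median - 0.5) > 1e-9:
            raise ValueError(
                f"arm {self.name!r}: survival at median is {s_at_median:.12f}, not 0.5; "
                "scale inconsistent with median"
            )

    def survival(self, t: np.ndarray | float) -> np.ndarray | float:
        """True Weibull survival function of this arm."""
        t = np.asarray(t, dtype=float)
        return np.exp(-((t / self.scale) ** self.shape))


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm design for a single endpoint under proportional hazards.

    Both arms share the Weibull shape, so the hazard ratio
    ``(scale_ctl / scale_trt) ** shape`` is constant in time.
    """

    endpoint: str
    treatment: ArmSpec
    control: ArmSpec
    target_hr: float
    censor_time: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_hr <= 1):
            raise ValueError("target_hr must lie in (0, 1]")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if abs(self.treatment.shape - self.control.shape) > 1e-9:
            raise ValueError("arms must share a Weibull shape (proportional hazards)")


def calibrate_weibull_pair(
    median_trt: float, median_ctl: float, hr: float
) -> tuple[float, float, float]:
    """Solve for the common-shape Weibull pair hitting both medians and the HR.

    For Weibull survival ``S(t) = exp(-(t/lambda)**k)`` with a shared shape
    ``k``, the hazard ratio of treatment vs control is
    ``(lambda_ctl / lambda_trt) ** k`` and each median is
    ``lambda * ln(2) ** (1/k)``.  Eliminating the scales gives the unique
    shape ``k = ln(hr) / ln(median_ctl / median_trt)``.

    Parameters
    ----------
    median_trt, median_ctl : arm medians in months.
    hr : target hazard ratio (treatment vs control) in ``(0, 1]``.

    Returns
    -------
    ``(shape, scale_trt, scale_ctl)``.

    Raises
    ------
    ValueError
        For non-positive inputs, ``hr == 1`` with distinct medians (no
        consistent shape exists), or ``hr < 1`` with ``median_trt`` not
        exceeding ``median_ctl``.
    """
    if min(median_trt, median_ctl, hr) <= 0:
        raise ValueError("medians and hr must be positive")
    if hr > 1:
        raise ValueError("hr must be <= 1 (treatment is the benefiting arm)")
    same_median = math.isclose(median_trt, median_ctl, rel_tol=1e-12)
    if math.isclose(hr, 1.0):
        if not same_median:
            raise ValueError("hr = 1 with distinct medians admits no common shape")
        shape = 1.0  # convention: identical exponential-shaped arms
    else:
        if same_median:
            raise ValueError("equal medians with hr < 1 admit no common shape")
        if median_trt < median_ctl:
            raise ValueError("hr < 1 requires median_trt > median_ctl")
        shape = math.log(hr) / math.log(median_ctl / median_trt)
    scale_trt = median_trt / math.log(2) ** (1.0 / shape)
    scale_ctl = median_ctl / math.log(2) ** (1.0 / shape)
    return shape, scale_trt, scale_ctl


def _design(
    endpoint: str,
    median_trt: float,
    median_ctl: float,
    hr: float,
    n_per_arm: int,
    censor_time: float,
    seed: int,
) -> TrialDesign:
    shape, scale_trt, scale_ctl = calibrate_weibull_pair(median_trt, median_ctl, hr)
    return TrialDesign(
        endpoint=endpoint,
        treatment=ArmSpec("treatment", n_per_arm, median_trt, shape, scale_trt),
        control=ArmSpec("control", n_per_arm, median_ctl, shape, scale_ctl),
        target_hr=hr,
        censor_time=censor_time,
        seed=seed,
    )


# Trial summaries the defaults are calibrated to: median PFS 15.0 vs 7.3
# months (HR 0.43), median OS 34 vs 27 months (HR 0.67), administrative
# censoring near the ~21-month median follow-up for PFS and the extended
# 34.2-month follow-up for OS.
PFS_MEDIANS = (15.0, 7.3)
PFS_HR = 0.43
OS_MEDIANS = (34.0, 27.0)
OS_HR = 0.67
DEFAULT_N_PER_ARM = 162
PFS_CENSOR_MONTHS = 21.4
OS_CENSOR_MONTHS = 34.2


def default_trial_design(
    endpoint: str, n_per_arm: int = DEFAULT_N_PER_ARM, seed: int = 0
) -> TrialDesign:
    """Calibrated default design for endpoint ``"pfs"`` or ``"os"``."""
    key = endpoint.lower()
    if key == "pfs":
        return _design("pfs", *PFS_MEDIANS, PFS_HR, n_per_arm, PFS_CENSOR_MONTHS, seed)
    if key == "os":
        return _design("os", *OS_MEDIANS, OS_HR, n_per_arm, OS_CENSOR_MONTHS, seed)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def generate_ipd(design: TrialDesign) -> dict[str, PseudoIPD]:
    """Simulate per-patient (time, event) records for both arms.

    Event times are Weibull draws; observation is truncated at the design's
    administrative censoring time.  Reproducible for a fixed design seed.

    Returns a dict mapping arm name to :class:`PseudoIPD`.
    """
    rng = np.random.default_rng(design.seed)
    out: dict[str, PseudoIPD] = {}
    for arm in (design.treatment, design.control):
        raw = arm.scale * rng.weibull(arm.shape, size=arm.n)
        time = np.minimum(raw, design.censor_time)
        event = (raw <= design.censor_time).astype(int)
        out[arm.name] = PseudoIPD(
            time=time, event=event, arm=arm.name, endpoint=design.endpoint
        )
    return out


def km_curve(ipd: PseudoIPD, risk_times: np.ndarray | list[float]) -> DigitizedCurve:
    """Product-limit curve plus numbers-at-risk, emulating a digitizer's output.

    Parameters
    ----------
    ipd : patient records.
    risk_times : month grid at which numbers at risk are tabulated (the
        published risk table under a KM plot).

    Returns
    -------
    :class:`DigitizedCurve` with step coordinates at each distinct observed
    event time (prefixed with ``(0, 1)``) and the risk table.
    """
    if len(ipd.time) == 0:
        raise ValueError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    sf = kmf.survival_function_.iloc[:, 0]
    # keep time 0 and distinct event times; drop censoring-only steps (no change)
    times = np.asarray(sf.index, dtype=float)
    surv = np.asarray(sf.values, dtype=float)
    keep = np.ones(len(times), dtype=bool)
    keep[1:] = np.diff(surv) < 0
    keep[0] = True
    coords = np.column_stack([times[keep], surv[keep]])
    # append the end of follow-up so the curve records where observation stops
    t_max = float(ipd.time.max())
    if coords[-1, 0] < t_max:
        coords = np.vstack([coords, [t_max, coords[-1, 1]]])
    risk_times = np.asarray(risk_times, dtype=float)
    n_at_risk = np.array(
        [int(np.sum(ipd.time >= rt)) for rt in risk_times], dtype=int
    )
    return DigitizedCurve(
        coords=coords,
        risk_table=np.column_stack([risk_times, n_at_risk]),
        n_total=len(ipd.time),
        arm=ipd.arm,
        endpoint=ipd.endpoint,
    )


def km_median(ipd: PseudoIPD) -> float:
    """Product-limit median survival time; ``nan`` if the curve never
    reaches 0.5 within follow-up."""
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    med = float(kmf.median_survival_time_)
    return math.nan if math.isinf(med) else med


def write_ipd_csv(ipds: dict[str, PseudoIPD] | list[PseudoIPD], path) -> None:
    """Write pseudo-IPD records as CSV: time, event, arm, endpoint."""
    if isinstance(ipds, dict):
        ipds = list(ipds.values())
    frames = [
        pd.DataFrame(
            {"time": ipd.time, "event": ipd.event, "arm": ipd.arm, "endpoint": ipd.endpoint}
        )
        for ipd in ipds
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
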