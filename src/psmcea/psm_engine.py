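"""Three-state partitioned survival engine.

State occupancy is read directly off the two fitted survival curves at
each cycle boundary: progression-free = the PFS curve (clamped to OS where
the fitted curves cross), dead = one minus the OS curve, progressed = the
remainder.  The trace runs until 99% of the cohort has died (lifetime
rule) or a fixed horizon, with half-cycle-averaged occupancy for accrual
and discounting at cycle midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ModelSettings", "StateTrace", "build_trace", "discount_factor", "DAYS_PER_MONTH"]

DAYS_PER_MONTH = 365.25 / 12.0
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ModelSettings:
    """Cycle, horizon, discounting and correction settings.

    Parameters
    ----------
    cycle_length_days : model cycle in days (default 28, the treatment
        schedule's cycle).
    discount_annual : annual discount rate for costs and outcomes
        (default 0.05).
    horizon_rule : ``"lifetime"`` (run until ``dead_fraction`` of the
        cohort has died) or ``"fixed"`` (run ``horizon_years``).
    horizon_years : fixed horizon in years (required when
        ``horizon_rule == "fixed"``).
    max_horizon_years : cap on the lifetime rule (default 40).
    half_cycle : average cycle-boundary occupancy for accrual (default on).
    dead_fraction : mortality fraction stopping the lifetime rule (0.99).
    """

    cycle_length_days: float = 28.0
    discount_annual: float = 0.05
    horizon_rule: str = "lifetime"
    horizon_years: float | None = None
    max_horizon_years: float = 40.0
    half_cycle: bool = True
    dead_fraction: float = 0.99

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        if not 0 <= self.discount_annual <= 0.08:
            raise ValueError("discount_annual must lie in [0, 0.08]")
        if self.horizon_rule not in ("lifetime", "fixed"):
            raise ValueError("horizon_rule must be 'lifetime' or 'fixed'")
        if self.horizon_rule == "fixed" and not self.horizon_years:
            raise ValueError("fixed horizon_rule requires horizon_years")
        if self.max_horizon_years < 1:
            raise ValueError("max_horizon_years must be >= 1")

    @property
    def cycle_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    def with_horizon(self, horizon_years: float | None) -> "ModelSettings":
        """Copy with a fixed horizon (or the lifetime rule when ``None``)."""
        if horizon_years is None:
            return replace(self, horizon_rule="lifetime", horizon_years=None)
        return replace(self, horizon_rule="fixed", horizon_years=horizon_years)


def discount_factor(t_years: np.ndarray | float, annual_rate: float) -> np.ndarray:
    """Continuous-exponent discount factor ``(1 + r)^(-t)``."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return (1.0 + annual_rate) ** (-t)


@dataclass
class StateTrace:
    """Per-cycle occupancy of the three health states.

    Boundary arrays (length ``n_cycles + 1``) hold occupancy at cycle
    starts; cycle arrays (length ``n_cycles``) hold the accrual-ready
    half-cycle-averaged occupancy, cycle midpoint times, and discount
    factors.
    """

    t_boundary: np.ndarray  # months at cycle starts, t[0] = 0
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    pfs_bar: np.ndarray
    pd_bar: np.ndarray
    t_mid_years: np.ndarray
    df: np.ndarray
    cycle_years: float
    cycle_months: float
    discount_annual: float
    horizon_capped: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.pfs_bar)

    def discount_factors(self, annual_rate: float) -> np.ndarray:
        """Cycle-midpoint discount factors under an alternative rate."""
        return discount_factor(self.t_mid_years, annual_rate)

    def life_years(self, discounted: bool = False) -> float:
        """(Discounted) life expectancy over the trace, in years."""
        w = self.df if discounted else 1.0
        return float(np.sum((self.pfs_bar + self.pd_bar) * w) * self.cycle_years)

    def to_frame(self):
        import pandas as pd_mod

        return pd_mod.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "t_months": self.t_boundary[:-1],
                "pfs": self.pfs[:-1],
                "pd": self.pd[:-1],
                "dead": self.dead[:-1],
                "pfs_bar": self.pfs_bar,
                "pd_bar": self.pd_bar,
                "df": self.df,
            }
        )


def build_trace(pfs_fit, os_fit, settings: ModelSettings) -> StateTrace:
    """Partition two survival curves into a discounted three-state trace.

    At each cycle boundary ``t``: progression-free occupancy is
    ``min(S_PFS(t), S_OS(t))`` (the clamp keeps the progressed-state share
    non-negative when fitted curves cross), dead is ``1 - S_OS(t)`` and
    progressed is the difference.  Under the lifetime rule the trace ends
    at the first boundary where the dead share reaches the stopping
    fraction; if the horizon cap intervenes first the trace is flagged.
    """
    cm = settings.cycle_months
    if settings.horizon_rule == "fixed":
        n_cycles = max(1, int(round(settings.horizon_years * 12.0 / cm)))
        capped = False
    else:
        max_cycles = int(np.ceil(settings.max_horizon_years * 12.0 / cm))
        # locate the stopping cycle on the full grid
        tgrid = np.arange(max_cycles + 1) * cm
        dead = 1.0 - np.asarray(os_fit.survival(tgrid), dtype=float)
        hit = np.nonzero(dead >= settings.dead_fraction)[0]
        if len(hit):
            n_cycles = max(1, int(hit[0]))
            capped = False
        else:
            n_cycles = max_cycles
            capped = True

    t = np.arange(n_cycles + 1) * cm
    s_os = np.clip(np.asarray(os_fit.survival(t), dtype=float), 0.0, 1.0)
    s_pfs = np.clip(np.asarray(pfs_fit.survival(t), dtype=float), 0.0, 1.0)
    pfs = np.minimum(s_pfs, s_os)
    dead = 1.0 - s_os
    pd_ = s_os - pfs

    if settings.half_cycle:
        pfs_bar = 0.5 * (pfs[:-1] + pfs[1:])
        pd_bar = 0.5 * (pd_[:-1] + pd_[1:])
    else:
        pfs_bar = pfs[:-1].copy()
        pd_bar = pd_[:-1].copy()

    t_mid_years = (t[:-1] + 0.5 * cm) / 12.0
    df = discount_factor(t_mid_years, settings.discount_annual)
    return StateTrace(
        t_boundary=t,
        pfs=pfs,
        pd=pd_,
        dead=dead,
        pfs_bar=pfs_bar,
        pd_bar=pd_bar,
        t_mid_years=t_mid_years,
        df=df,
        cycle_years=settings.cycle_years,
        cycle_months=cm,
        discount_annual=settings.discount_annual,
        horizon_capped=capped,
    )
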