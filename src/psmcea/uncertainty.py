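"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the assembled model at the low and high end of each
parameter's range (±20% of base for costs, utilities and disutilities;
0–8% for the discount rate) and orders the tornado by ICER spread.

The PSA assigns gamma distributions to costs and beta distributions to
utilities, disutilities and the (range-scaled) discount rate, derives the
hyper-parameters by moment matching with sd = range / (2 * 1.96) —
treating the range as a 95% interval — and Monte-Carlo samples all
parameters jointly, re-running the economic layer over the fixed survival
traces each draw.  Survival-curve parameter uncertainty is deliberately
not resampled: the distributions cover the cost/utility/probability
inputs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from psmcea.economics import EconomicInputs
from psmcea.pipeline import CEModel

__all__ = [
    "ParamSpec",
    "PSAResult",
    "dsa_ranges",
    "one_way",
    "tornado",
    "moments_to_gamma",
    "moments_to_beta",
    "run_psa",
    "ceac",
]

_Z95 = 2 * 1.96  # range treated as a 95% interval


@dataclass
class ParamSpec:
    """One uncertain parameter: base value, DSA range, PSA distribution.

    ``dist`` is ``"gamma"`` (non-negative costs) or ``"beta"`` (values on
    ``[0, upper]``; ``upper`` is 1 for utilities and the top of the range
    for the discount rate).  Hyper-parameters are derived lazily by moment
    matching.
    """

    name: str
    base: float
    low: float
    high: float
    dist: str = "gamma"
    upper: float = 1.0  # support upper bound for beta-distributed parameters

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.dist not in ("gamma", "beta"):
            raise ValueError(f"{self.name}: dist must be 'gamma' or 'beta'")
        if self.dist == "gamma" and self.low < 0:
            raise ValueError(f"{self.name}: gamma support is non-negative")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / _Z95

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw from the assigned distribution (clamped to valid support)."""
        if self.sd == 0:
            return np.full(size, self.base)
        if self.dist == "gamma":
            shape, rate = moments_to_gamma(self.base, self.low, self.high)
            return rng.gamma(shape, 1.0 / rate, size=size)
        a, b = moments_to_beta(
            self.base / self.upper,
            self.low / self.upper,
            self.high / self.upper,
        )
        return self.upper * np.clip(rng.beta(a, b, size=size), 0.0, 1.0)


def moments_to_gamma(mean: float, low: float, high: float) -> tuple[float, float]:
    """Gamma (shape, rate) matching mean and sd = (high - low) / 3.92."""
    sd = (high - low) / _Z95
    if sd <= 0:
        raise ValueError("degenerate range: sd = 0")
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    return shape, rate


def moments_to_beta(mean: float, low: float, high: float) -> tuple[float, float]:
    """Beta (a, b) matching mean and sd = (high - low) / 3.92 on [0, 1].

    The mean is clamped into (0, 1); if the implied variance exceeds the
    feasible Bernoulli bound ``mean * (1 - mean)`` the sd is shrunk to 99%
    of that bound (the match is then approximate, flagged by the caller's
    tolerance).
    """
    sd = (high - low) / _Z95
    if sd <= 0:
        raise ValueError("degenerate range: sd = 0")
    m = min(max(mean, 1e-9), 1 - 1e-9)
    var_max = m * (1 - m)
    var = min(sd**2, 0.99 * var_max)
    nu = var_max / var - 1.0
    return m * nu, (1 - m) * nu


def dsa_ranges(inputs: EconomicInputs) -> list[ParamSpec]:
    """ParamSpecs for every tabulated input plus the discount rate.

    Costs, utilities and disutilities get ±20% ranges around base (utility
    highs may exceed 1 on paper; evaluation clamps); the discount rate
    spans 0–8% with a beta distribution scaled to that range.
    """
    specs: list[ParamSpec] = []
    for name, c in inputs.drug_cost_per_cycle.items():
        specs.append(ParamSpec(f"cost_{name}", c, 0.8 * c, 1.2 * c, "gamma"))
    for name, c in inputs.other_cost_per_cycle.items():
        specs.append(ParamSpec(f"cost_{name}", c, 0.8 * c, 1.2 * c, "gamma"))
    for ae in inputs.ae_profile:
        specs.append(ParamSpec(f"ae_cost_{ae.name}", ae.cost, 0.8 * ae.cost, 1.2 * ae.cost, "gamma"))
    for state, u in inputs.utilities.items():
        specs.append(ParamSpec(f"utility_{state}", u, 0.8 * u, 1.2 * u, "beta"))
    for ae in inputs.ae_profile:
        specs.append(
            ParamSpec(
                f"disutility_{ae.name}", ae.disutility, 0.8 * ae.disutility, 1.2 * ae.disutility, "beta"
            )
        )
    specs.append(ParamSpec("discount_rate", 0.05, 0.0, 0.08, "beta", upper=0.08))
    return specs


def one_way(param: ParamSpec, model: CEModel) -> tuple[float | None, float | None]:
    """ICERs at the low and high end of one parameter's range.

    Utility highs above 1 are clamped by the override layer.  Either ICER
    is ``None`` if the incremental QALYs vanish at that end.
    """
    lo = model.evaluate({param.name: param.low})
    hi = model.evaluate({param.name: param.high})
    return lo.icer, hi.icer


def tornado(model: CEModel, specs: list[ParamSpec] | None = None) -> pd.DataFrame:
    """One-way DSA across all parameters, ordered by ICER spread.

    Entries whose incremental QALYs change sign within the range are
    flagged (``valid = False``) and sorted last.
    """
    specs = specs if specs is not None else dsa_ranges(model.inputs)
    base_icer = model.base_icer()
    rows = []
    for p in specs:
        icer_lo, icer_hi = one_way(p, model)
        valid = icer_lo is not None and icer_hi is not None
        spread = abs(icer_hi - icer_lo) if valid else np.nan
        rows.append(
            {
                "parameter": p.name,
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "spread": spread,
                "valid": valid,
            }
        )
    df = pd.DataFrame(rows)
    df["base_icer"] = base_icer
    return df.sort_values(
        ["valid", "spread"], ascending=[False, False], ignore_index=True
    )


@dataclass
class PSAResult:
    """Monte-Carlo draws of incremental cost and QALYs."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    n_iter: int
    samples: pd.DataFrame | None = field(default=None, repr=False)

    def nmb(self, wtp: float) -> np.ndarray:
        return wtp * self.delta_qaly - self.delta_cost

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly})


def run_psa(
    model: CEModel,
    n_iter: int = 10_000,
    seed: int = 0,
    specs: list[ParamSpec] | None = None,
    keep_samples: bool = False,
) -> PSAResult:
    """Probabilistic sensitivity analysis over the fixed survival traces.

    Each iteration samples every parameter independently from its
    distribution and re-runs the economic layer; survival fits (hence the
    occupancy traces) stay at their point estimates.  Reproducible for a
    fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    specs = specs if specs is not None else dsa_ranges(model.inputs)
    rng = np.random.default_rng(seed)
    draws = {p.name: p.sample(rng, n_iter) for p in specs}
    dc = np.empty(n_iter)
    de = np.empty(n_iter)
    for i in range(n_iter):
        res = model.evaluate({k: v[i] for k, v in draws.items()})
        dc[i] = res.delta_cost
        de[i] = res.delta_qaly
    samples = pd.DataFrame(draws) if keep_samples else None
    return PSAResult(delta_cost=dc, delta_qaly=de, seed=seed, n_iter=n_iter, samples=samples)


def ceac(psa: PSAResult, wtp_grid: np.ndarray | list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the probability of cost-
    effectiveness is the fraction of draws with positive net monetary
    benefit.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty wtp grid")
    prob = [float(np.mean(psa.nmb(w) > 0)) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})
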