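"""Scenario analyses: price sweep and break-even, horizon sweep, utilities, regional thresholds.

The price scenarios reprice only the novel agent (9 mg once daily on days
1–28, i.e. 28 tablets per 28-day cycle, so the per-tablet baseline is the
per-cycle cost divided by 28); all comparator prices stay fixed.  Because
incremental QALYs do not depend on prices and incremental cost is affine
in the per-tablet price, the ICER is affine and strictly increasing in
price, which makes the break-even price (ICER equal to the
willingness-to-pay threshold) unique and safely found by bisection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from psmcea.economics import CEResult
from psmcea.pipeline import CEModel

__all__ = [
    "TABLETS_PER_CYCLE",
    "price_sweep",
    "break_even_price",
    "horizon_sweep",
    "utility_scenario",
    "regional_wtp",
]

TABLETS_PER_CYCLE = 28
PRICED_DRUG = "inavolisib"


def per_tablet_price(model: CEModel) -> float:
    """Baseline per-tablet price of the repriced drug."""
    return model.inputs.drug_cost_per_cycle[PRICED_DRUG] / TABLETS_PER_CYCLE


def _icer_at_reduction(model: CEModel, reduction: float) -> CEResult:
    base = model.inputs.drug_cost_per_cycle[PRICED_DRUG]
    return model.evaluate({f"cost_{PRICED_DRUG}": base * (1.0 - reduction)})


def price_sweep(model: CEModel, reductions: np.ndarray | list[float] | None = None) -> pd.DataFrame:
    """ICER at a grid of price reductions of the novel agent.

    ``reductions`` are fractions of the baseline price removed (default
    0 to 95% in 5% steps).  Returns columns: reduction, per_tablet_price,
    delta_cost, delta_qaly, icer.
    """
    if reductions is None:
        reductions = np.arange(0.0, 0.96, 0.05)
    reductions = np.asarray(reductions, dtype=float)
    if np.any((reductions < 0) | (reductions > 1)):
        raise ValueError("reductions must lie in [0, 1]")
    p0 = per_tablet_price(model)
    rows = []
    for r in reductions:
        res = _icer_at_reduction(model, r)
        rows.append(
            {
                "reduction": float(r),
                "per_tablet_price": p0 * (1.0 - r),
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_qaly,
                "icer": res.icer,
            }
        )
    return pd.DataFrame(rows)


def break_even_price(
    model: CEModel,
    wtp: float | None = None,
    rel_tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Per-tablet price at which the ICER equals the threshold (bisection).

    Requires the base-price ICER to exceed the threshold and the
    zero-price ICER to undercut it; otherwise no break-even price exists
    on the bracket and a ``ValueError`` is raised.
    """
    wtp = wtp if wtp is not None else model.inputs.wtp
    icer_base = _icer_at_reduction(model, 0.0).icer
    icer_zero = _icer_at_reduction(model, 1.0).icer
    if icer_base is None or icer_zero is None:
        raise ValueError("incremental QALYs vanish; break-even undefined")
    if not (icer_zero < wtp < icer_base):
        raise ValueError(
            f"no break-even on bracket: ICER at zero price {icer_zero:.2f}, "
            f"at base price {icer_base:.2f}, threshold {wtp:.2f}"
        )
    p0 = per_tablet_price(model)
    lo, hi = 0.0, p0  # ICER increasing in price
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        icer = _icer_at_reduction(model, 1.0 - mid / p0).icer
        if abs(icer - wtp) <= rel_tol * wtp:
            return mid
        if icer > wtp:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def horizon_sweep(
    model: CEModel, horizons: list[float | None] = (5, 10, 15, 20, None)
) -> pd.DataFrame:
    """Per-arm totals and ICER across fixed horizons plus lifetime (None)."""
    rows = []
    for h in horizons:
        res = model.evaluate(horizon_years=h)
        rows.append(
            {
                "horizon_years": np.inf if h is None else float(h),
                "horizon": "lifetime" if h is None else f"{h:g}y",
                "cost_treatment": res.treatment.total_cost,
                "cost_control": res.control.total_cost,
                "qaly_treatment": res.treatment.total_qaly,
                "qaly_control": res.control.total_qaly,
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_qaly,
                "icer": res.icer,
            }
        )
    return pd.DataFrame(rows)


def utility_scenario(model: CEModel, u_pfs: float, u_pd: float) -> CEResult:
    """Re-run with substituted health-state utilities; costs are untouched."""
    if not (0 <= u_pfs <= 1 and 0 <= u_pd <= 1):
        raise ValueError("utilities must lie in [0, 1]")
    return model.evaluate({"utility_pfs": u_pfs, "utility_pd": u_pd})


def regional_wtp(ce: CEResult, thresholds: dict[str, float]) -> pd.DataFrame:
    """Cost-effectiveness verdict per region-specific threshold.

    Thresholds (e.g. three times a province's GDP per capita) are plain
    config inputs.  Returns columns: region, wtp, nmb, cost_effective.
    """
    rows = []
    for region, w in thresholds.items():
        if w <= 0:
            raise ValueError(f"threshold for {region!r} must be positive")
        nmb = w * ce.delta_qaly - ce.delta_cost
        verdict = ce.icer is not None and ce.delta_qaly > 0 and ce.icer <= w
        rows.append({"region": region, "wtp": w, "nmb": nmb, "cost_effective": verdict})
    return pd.DataFrame(rows)
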