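"""Assembled cost-effectiveness model: fits + settings + economics.

:class:`CEModel` wires one survival fit per arm and endpoint into the
partitioned-survival engine and exposes a single ``evaluate`` closure the
sensitivity and scenario analyses re-run with parameter overrides.  State
occupancy traces are cached per horizon; parameter overrides touch only
the economic layer (plus the discount rate, which re-weights the cached
trace), so a full re-evaluation is cheap.

Override keys
-------------
``cost_<drug>`` and ``cost_<item>``
    per-cycle USD amounts (drugs and routine items).
``utility_pfs`` / ``utility_pd``
    health-state utilities, clamped to [0, 1].
``ae_cost_<name>`` / ``disutility_<name>``
    adverse-event unit cost and utility decrement.
``discount_rate``
    annual discount rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from psmcea.economics import (
    CONTROL,
    TREATMENT,
    CEResult,
    EconomicInputs,
    accrue,
    default_inputs,
    incremental,
)
from psmcea.psm_engine import ModelSettings, StateTrace, build_trace
from psmcea.survival_fit import weibull_fit_from_params
from psmcea.synthetic_trial import default_trial_design

__all__ = ["CEModel", "build_model"]


def _apply_overrides(inputs: EconomicInputs, overrides: dict) -> EconomicInputs:
    out = inputs.copy()
    ae_by_name = {ae.name: ae for ae in out.ae_profile}
    for key, value in overrides.items():
        if key == "discount_rate":
            continue  # handled by the caller
        if key.startswith("utility_"):
            state = key.removeprefix("utility_")
            if state not in out.utilities:
                raise KeyError(f"unknown utility override {key!r}")
            out.utilities[state] = min(max(float(value), 0.0), 1.0)
        elif key.startswith("ae_cost_"):
            name = key.removeprefix("ae_cost_")
            ae_by_name[name].cost = float(value)
        elif key.startswith("disutility_"):
            name = key.removeprefix("disutility_")
            ae_by_name[name].disutility = float(value)
        elif key.startswith("cost_"):
            name = key.removeprefix("cost_")
            if name in out.drug_cost_per_cycle:
                out.drug_cost_per_cycle[name] = float(value)
            elif name in out.other_cost_per_cycle:
                out.other_cost_per_cycle[name] = float(value)
            else:
                raise KeyError(f"unknown cost override {key!r}")
        else:
            raise KeyError(f"unknown override {key!r}")
    return out


@dataclass
class CEModel:
    """Survival fits, model settings and economic inputs, ready to evaluate."""

    fits: dict[tuple[str, str], object]  # (endpoint, arm) -> fit with .survival
    settings: ModelSettings
    inputs: EconomicInputs
    _trace_cache: dict = field(default_factory=dict, repr=False)

    def trace(self, arm: str, horizon_years: float | None = None) -> StateTrace:
        """State trace for one arm (cached per horizon)."""
        key = (arm, horizon_years)
        if key not in self._trace_cache:
            settings = (
                self.settings
                if horizon_years is None and self.settings.horizon_rule == "lifetime"
                else self.settings.with_horizon(horizon_years)
            )
            self._trace_cache[key] = build_trace(
                self.fits[("pfs", arm)], self.fits[("os", arm)], settings
            )
        return self._trace_cache[key]

    def evaluate(
        self,
        overrides: dict | None = None,
        horizon_years: float | None = None,
        wtp: float | None = None,
    ) -> CEResult:
        """Run the economic layer and return the incremental summary.

        ``horizon_years=None`` means the model's own horizon rule
        (lifetime by default); a number truncates both traces.
        """
        overrides = overrides or {}
        inputs = _apply_overrides(self.inputs, overrides) if overrides else self.inputs
        discount = overrides.get("discount_rate")
        if discount is not None:
            discount = float(discount)
        res = {
            arm: accrue(self.trace(arm, horizon_years), arm, inputs, discount_annual=discount)
            for arm in (TREATMENT, CONTROL)
        }
        return incremental(res[TREATMENT], res[CONTROL], wtp if wtp is not None else inputs.wtp)

    def base_icer(self) -> float:
        icer = self.evaluate().icer
        if icer is None:
            raise ValueError("base-case incremental QALYs are zero; ICER undefined")
        return icer


def build_model(
    inputs: EconomicInputs | None = None,
    settings: ModelSettings | None = None,
    fits: dict[tuple[str, str], object] | None = None,
) -> CEModel:
    """Assemble a model; defaults to the calibrated Weibull survival pair.

    Without explicit ``fits``, the survival layer uses the exact Weibull
    pair calibrated to the published PFS and OS medians and hazard ratios
    (no sampling noise), which makes the default model deterministic.
    """
    inputs = inputs if inputs is not None else default_inputs()
    settings = settings if settings is not None else ModelSettings()
    if fits is None:
        fits = {}
        for endpoint in ("pfs", "os"):
            design = default_trial_design(endpoint)
            for arm_spec in (design.treatment, design.control):
                fits[(endpoint, arm_spec.name)] = weibull_fit_from_params(
                    arm_spec.shape, arm_spec.scale
                )
    return CEModel(fits=fits, settings=settings, inputs=inputs)
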