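"""Pseudo-individual-patient-data reconstruction from digitized KM curves.

Published Kaplan-Meier plots carry more information than the survival
probabilities alone: combined with the numbers-at-risk table printed under
the plot, the step coordinates over-determine the event and censoring
pattern within each risk-table interval.  The interval algorithm
implemented here (the de-facto standard for secondary survival analyses)
iterates, per interval, on the number of censorings — spread uniformly
within the interval — until the implied number at risk at the next
risk-table time matches the table, while events at each click time are
chosen so the recomputed product-limit estimate tracks the digitized
survival probabilities.

Without a risk table the problem is under-determined; the fallback assumes
no censoring before the end of follow-up, with every remaining patient
administratively censored at the last digitized time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DigitizedCurve", "PseudoIPD", "reconstruct", "validate_reconstruction"]


@dataclass
class PseudoIPD:
    """Per-patient (time, event) records for one arm and endpoint."""

    time: np.ndarray
    event: np.ndarray
    arm: str = ""
    endpoint: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(self.time < 0):
            raise ValueError("times must be non-negative")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event, "arm": self.arm, "endpoint": self.endpoint}
        )


@dataclass
class DigitizedCurve:
    """Digitized KM step coordinates plus the numbers-at-risk table.

    ``coords`` is an ``(m, 2)`` array of ``(time, survival)`` clicks;
    ``risk_table`` an ``(r, 2)`` array of ``(time, n_at_risk)``.  Click
    times are sorted and deduplicated keeping the minimum survival per time
    (digitizer output is noisy); a ``(0, 1)`` anchor is inserted if absent.
    """

    coords: np.ndarray
    risk_table: np.ndarray | None
    n_total: int
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if np.any((c[:, 1] < -1e-9) | (c[:, 1] > 1 + 1e-9)):
            raise ValueError("survival values must lie in [0, 1]")
        c[:, 1] = np.clip(c[:, 1], 0.0, 1.0)
        order = np.argsort(c[:, 0], kind="stable")
        c = c[order]
        # dedupe: keep min survival per time
        times, inv = np.unique(c[:, 0], return_inverse=True)
        surv = np.full(len(times), np.inf)
        np.minimum.at(surv, inv, c[:, 1])
        # enforce monotone non-increasing survival
        surv = np.minimum.accumulate(surv)
        if times[0] > 0:
            times = np.insert(times, 0, 0.0)
            surv = np.insert(surv, 0, 1.0)
        else:
            surv[0] = 1.0
        self.coords = np.column_stack([times, surv])
        if self.risk_table is not None:
            rt = np.asarray(self.risk_table, dtype=float).reshape(-1, 2)
            rt = rt[np.argsort(rt[:, 0], kind="stable")]
            if np.any(np.diff(rt[:, 1]) > 0):
                raise ValueError("numbers at risk must be non-increasing")
            if abs(rt[0, 0]) < 1e-12 and int(round(rt[0, 1])) != self.n_total:
                raise ValueError("n_at_risk at time 0 must equal n_total")
            self.risk_table = rt
        if self.n_total < 1:
            raise ValueError("n_total must be positive")

    def survival_at(self, t: np.ndarray | float) -> np.ndarray:
        """Step-function survival at arbitrary times (right-continuous steps)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.coords[:, 0], t, side="right") - 1
        idx = np.clip(idx, 0, len(self.coords) - 1)
        return self.coords[idx, 1]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame | None]:
        curve = pd.DataFrame(self.coords, columns=["time", "survival"])
        risk = None
        if self.risk_table is not None:
            risk = pd.DataFrame(self.risk_table, columns=["time", "n_at_risk"])
            risk["n_at_risk"] = risk["n_at_risk"].astype(int)
        return curve, risk


def _even_times(t_lo: float, t_hi: float, n: int) -> np.ndarray:
    """``n`` censoring times spread evenly over ``[t_lo, t_hi)``."""
    if n <= 0:
        return np.empty(0)
    return t_lo + (np.arange(1, n + 1) - 0.5) * ((t_hi - t_lo) / n)


def _walk_interval(
    t: np.ndarray,
    s: np.ndarray,
    idx: np.ndarray,
    t_lo: float,
    t_hi: float,
    n_risk_start: int,
    n_cen: int,
    km_prev: float,
) -> tuple[np.ndarray, float, int]:
    """Event counts per click for a fixed censoring count in one interval.

    Censorings are placed at evenly spaced times; at each click the event
    count is the rounded solution of the product-limit step matching the
    digitized survival value.  Returns (events per click, KM at interval
    end, implied n at risk at ``t_hi``).
    """
    m = len(idx)
    cen_times = _even_times(t_lo, t_hi, n_cen)
    cen_per_click = np.zeros(m, dtype=int)
    bounds = np.append(t[idx][1:], t_hi)
    for ct in cen_times:
        k = int(np.searchsorted(bounds, ct, side="right"))
        cen_per_click[min(k, m - 1)] += 1
    d = np.zeros(m, dtype=int)
    n_hat = n_risk_start
    km_last = km_prev
    for j in range(m):
        if n_hat > 0 and km_last > 0:
            dj = int(round(n_hat * (1.0 - s[idx[j]] / km_last)))
        else:
            dj = 0
        dj = int(np.clip(dj, 0, n_hat))
        d[j] = dj
        if dj > 0:
            km_last = km_last * (1.0 - dj / n_hat)
        n_hat -= dj + cen_per_click[j]
    return d, cen_per_click, km_last, n_hat


def _solve_interval(
    t: np.ndarray,
    s: np.ndarray,
    idx: np.ndarray,
    t_lo: float,
    t_hi: float,
    n_risk_start: int,
    n_risk_end: int | None,
    km_prev: float,
):
    """Find the censoring count matching the next at-risk number.

    Follows the fixed-point iteration on the censoring count; if the
    iteration cycles without an exact match (integer rounding), scans a
    neighbourhood and keeps the count minimizing the at-risk mismatch.
    """
    if n_risk_end is None:
        d, cen, km, n_hat = _walk_interval(
            t, s, idx, t_lo, t_hi, n_risk_start, 0, km_prev
        )
        return d, cen, km, n_hat
    s_end = s[idx[-1]]
    frac = s_end / km_prev if km_prev > 0 else 0.0
    guess = int(round(n_risk_start * frac)) - n_risk_end
    best = None
    seen: set[int] = set()
    n_cen = int(np.clip(guess, 0, n_risk_start))
    while n_cen not in seen:
        seen.add(n_cen)
        d, cen, km, n_hat = _walk_interval(
            t, s, idx, t_lo, t_hi, n_risk_start, n_cen, km_prev
        )
        diff = n_hat - n_risk_end
        if best is None or abs(diff) < abs(best[0]):
            best = (diff, d, cen, km, n_hat)
        if diff == 0:
            break
        n_cen = int(np.clip(n_cen + diff, 0, n_risk_start))
    if best[0] != 0:
        # local scan around the best candidate for an exact integer match
        base_cen = int(best[2].sum())
        for cand in range(max(0, base_cen - 5), min(n_risk_start, base_cen + 5) + 1):
            if cand in seen:
                continue
            d, cen, km, n_hat = _walk_interval(
                t, s, idx, t_lo, t_hi, n_risk_start, cand, km_prev
            )
            diff = n_hat - n_risk_end
            if abs(diff) < abs(best[0]):
                best = (diff, d, cen, km, n_hat)
            if diff == 0:
                break
    if abs(best[0]) > 1:
        raise ValueError(
            f"infeasible curve/risk-table combination in interval "
            f"[{t_lo}, {t_hi}): implied n at risk {best[4]} vs table {n_risk_end}"
        )
    return best[1], best[2], best[3], best[4]


def reconstruct(curve: DigitizedCurve) -> PseudoIPD:
    """Invert a digitized KM curve into per-patient (time, event) records.

    With a risk table, the interval algorithm described in the module
    docstring is applied per risk-table interval; patients still at risk
    after the last click are censored at the end of follow-up.
    Reconstruction is deterministic: censorings are placed at evenly spaced
    times within each interval, no randomness is involved.

    Raises
    ------
    ValueError
        If the curve and risk table are jointly infeasible (the table
        demands more patients at risk than the curve admits).
    """
    t = curve.coords[:, 0]
    s = curve.coords[:, 1]
    n_total = curve.n_total

    if curve.risk_table is not None and len(curve.risk_table) > 0:
        risk_t = np.asarray(curve.risk_table[:, 0], dtype=float)
        risk_n = np.asarray(curve.risk_table[:, 1], dtype=int)
    else:
        risk_t = np.array([t[0]])
        risk_n = np.array([n_total])

    t_last = float(t[-1])
    ev_times: list[float] = []
    cen_times: list[float] = []
    km = 1.0
    n_risk = int(risk_n[0])
    for i in range(len(risk_t)):
        t_lo = float(risk_t[i])
        last_interval = i == len(risk_t) - 1
        t_hi = t_last if last_interval or risk_t[i + 1] > t_last else float(risk_t[i + 1])
        if not last_interval:
            t_hi = float(risk_t[i + 1])
        n_next = None if last_interval else int(risk_n[i + 1])
        if n_next is not None and n_next > n_risk:
            raise ValueError(
                f"infeasible risk table in interval [{t_lo}, {t_hi}): "
                f"n at risk rises from {n_risk} to {n_next}"
            )
        sel = (t >= t_lo) & ((t <= t_hi) if last_interval else (t < t_hi))
        idx = np.where(sel)[0]
        if len(idx) == 0:
            if n_next is not None:
                n_cen = n_risk - n_next  # pure-censoring interval, no clicks
                cen_times.extend(_even_times(t_lo, t_hi, n_cen))
                n_risk = n_next
            continue
        d, cen, km, n_hat = _solve_interval(
            t, s, idx, t_lo, t_hi, n_risk, n_next, km
        )
        # emit censorings within the click subinterval they were allocated
        # to (after that click's events), matching the solving walk
        sub_bounds = np.append(t[idx][1:], t_hi)
        for j, k in enumerate(idx):
            ev_times.extend([float(t[k])] * int(d[j]))
            cen_times.extend(_even_times(float(t[k]), float(sub_bounds[j]), int(cen[j])))
        n_risk = n_hat

    n_used = len(ev_times) + len(cen_times)
    if n_used > n_total:
        raise ValueError(
            f"reconstruction implied {n_used} patients but curve has n_total={n_total}"
        )
    # patients never observed to fail: administrative censoring at follow-up end
    cen_times.extend([t_last] * (n_total - n_used))

    time = np.array(ev_times + cen_times, dtype=float)
    event = np.concatenate(
        [np.ones(len(ev_times), dtype=int), np.zeros(len(cen_times), dtype=int)]
    )
    order = np.argsort(time, kind="stable")
    return PseudoIPD(
        time=time[order],
        event=event[order],
        arm=curve.arm,
        endpoint=curve.endpoint,
        source="reconstructed",
    )


def validate_reconstruction(curve: DigitizedCurve, ipd: PseudoIPD) -> dict:
    """Read-only check of a reconstruction against its source curve.

    Returns the sup-norm deviation between the KM estimate recomputed from
    ``ipd`` and the digitized coordinates (at the click times), per-risk-time
    at-risk mismatches, and the record-count balance.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    t_clicks = curve.coords[:, 0]
    km_hat = np.asarray(kmf.survival_function_at_times(t_clicks), dtype=float)
    max_dev = float(np.max(np.abs(km_hat - curve.coords[:, 1])))
    risk_mismatch = {}
    if curve.risk_table is not None:
        for rt, rn in curve.risk_table:
            implied = int(np.sum(ipd.time >= rt))
            risk_mismatch[float(rt)] = implied - int(rn)
    return {
        "max_km_deviation": max_dev,
        "risk_mismatch": risk_mismatch,
        "n_records": len(ipd),
        "n_expected": curve.n_total,
    }
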