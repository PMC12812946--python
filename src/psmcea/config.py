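"""Run configuration: YAML/JSON schema, validation, and the full pipeline.

A run is described by one config file with blocks for the survival source
(synthetic trial design XOR digitized-curve CSV paths), model settings,
economic inputs, and the sensitivity/scenario analyses.  Defaults mirror
the base case; a minimal config is just ``survival: {source: synthetic}``.

The single global seed expands into fixed per-stage child seeds (one per
endpoint for data generation, one for the PSA), so toggling the PSA on or
off never perturbs the synthetic data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from psmcea import economics
from psmcea.economics import AdverseEvent, EconomicInputs, default_inputs
from psmcea.km_reconstruct import DigitizedCurve, reconstruct
from psmcea.pipeline import CEModel, build_model
from psmcea.psm_engine import ModelSettings
from psmcea.survival_fit import fit_candidates, weibull_fit_from_params
from psmcea.synthetic_trial import default_trial_design, generate_ipd, km_curve

__all__ = ["RunConfig", "load_config", "run_pipeline"]

logger = logging.getLogger("psmcea")

# fixed child-seed offsets per stage
_SEED_PFS, _SEED_OS, _SEED_PSA = 1, 2, 3

ARMS = (economics.TREATMENT, economics.CONTROL)
ENDPOINTS = ("pfs", "os")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    output_dir: str = "psmcea_out"
    survival_source: str = "synthetic"  # "synthetic" | "files"
    n_per_arm: int = 162
    curve_files: dict[str, dict[str, str]] = field(default_factory=dict)
    use_calibrated_weibull: bool = False
    knot_counts: tuple[int, ...] = (0, 1, 2, 3)
    criterion: str = "aic"
    settings: ModelSettings = field(default_factory=ModelSettings)
    inputs: EconomicInputs = field(default_factory=default_inputs)
    dsa_enabled: bool = True
    psa_enabled: bool = True
    psa_iterations: int = 10_000
    price_reductions: list[float] | None = None
    horizons: list[float | None] = field(default_factory=lambda: [5, 10, 15, 20, None])
    alt_utilities: tuple[float, float] | None = (0.736, 0.630)
    regional_thresholds: dict[str, float] = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    def config_hash(self) -> str:
        # fingerprint of the modelling content; artifact location excluded
        content = {k: v for k, v in self.raw.items() if k != "output_dir"}
        blob = json.dumps(content, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"config key {key!r}: {msg}")


def _parse_inputs(block: dict) -> EconomicInputs:
    base = default_inputs()
    if not block:
        return base
    for key in ("drug_cost_per_cycle", "other_cost_per_cycle"):
        if key in block:
            getattr(base, key).update({k: float(v) for k, v in block[key].items()})
    if "utilities" in block:
        u = block["utilities"] or {}
        _require(set(u) >= {"pfs", "pd"}, "economics.utilities",
                 "must define both 'pfs' and 'pd'")
        base.utilities = {k: float(v) for k, v in u.items()}
    if "ae_profile" in block:
        base.ae_profile = [
            AdverseEvent(
                name=ae["name"],
                cost=float(ae["cost"]),
                disutility=float(ae["disutility"]),
                incidence={k: float(v) for k, v in ae.get("incidence", {}).items()},
            )
            for ae in block["ae_profile"]
        ]
    for key in ("wtp", "ae_mode", "ae_duration_cycles"):
        if key in block:
            setattr(base, key, block[key])
    base.__post_init__()
    return base


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    return parse_config(raw, base_dir=path.parent)


def parse_config(raw: dict, base_dir: Path | None = None) -> RunConfig:
    surv = raw.get("survival", {}) or {}
    source = surv.get("source", "synthetic")
    _require(source in ("synthetic", "files"), "survival.source",
             "must be 'synthetic' or 'files'")
    curve_files: dict[str, dict[str, str]] = {}
    if source == "files":
        files = surv.get("files")
        _require(bool(files), "survival.files", "required when source is 'files'")
        _require("design" not in surv, "survival",
                 "exactly one survival source: files XOR synthetic design")
        for ep in ENDPOINTS:
            _require(ep in files, f"survival.files.{ep}", "missing endpoint block")
            curve_files[ep] = {}
            for arm in ARMS:
                _require(arm in files[ep], f"survival.files.{ep}.{arm}", "missing arm")
                p = Path(files[ep][arm])
                if base_dir is not None and not p.is_absolute():
                    p = base_dir / p
                _require(p.exists(), f"survival.files.{ep}.{arm}", f"file not found: {p}")
                curve_files[ep][arm] = str(p)

    settings_block = raw.get("settings", {}) or {}
    settings = ModelSettings(
        cycle_length_days=settings_block.get("cycle_length_days", 28.0),
        discount_annual=settings_block.get("discount_annual", 0.05),
        horizon_rule=settings_block.get("horizon_rule", "lifetime"),
        horizon_years=settings_block.get("horizon_years"),
        max_horizon_years=settings_block.get("max_horizon_years", 40.0),
        half_cycle=settings_block.get("half_cycle", True),
        dead_fraction=settings_block.get("dead_fraction", 0.99),
    )
    inputs = _parse_inputs(raw.get("economics", {}) or {})
    psa = raw.get("psa", {}) or {}
    dsa = raw.get("dsa", {}) or {}
    scen = raw.get("scenarios", {}) or {}
    alt_u = scen.get("alt_utilities", {"pfs": 0.736, "pd": 0.630})
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "psmcea_out")),
        survival_source=source,
        n_per_arm=int(surv.get("n_per_arm", 162)),
        curve_files=curve_files,
        use_calibrated_weibull=bool(surv.get("use_calibrated_weibull", False)),
        knot_counts=tuple(surv.get("knot_counts", (0, 1, 2, 3))),
        criterion=surv.get("criterion", "aic"),
        settings=settings,
        inputs=inputs,
        dsa_enabled=bool(dsa.get("enabled", True)),
        psa_enabled=bool(psa.get("enabled", True)),
        psa_iterations=int(psa.get("iterations", 10_000)),
        price_reductions=scen.get("price_reductions"),
        horizons=scen.get("horizons", [5, 10, 15, 20, None]),
        alt_utilities=(float(alt_u["pfs"]), float(alt_u["pd"])) if alt_u else None,
        regional_thresholds={k: float(v) for k, v in scen.get("regional_wtp", {}).items()},
        raw=raw,
    )


def _read_curve(path: str, arm: str, endpoint: str) -> DigitizedCurve:
    """Read a digitized curve CSV (time, survival) plus optional risk table.

    A companion ``<stem>_risk.csv`` (time, n_at_risk) is picked up when
    present; ``n_total`` comes from the risk table's first row, else a
    ``# n_total=`` header comment is required.
    """
    p = Path(path)
    df = pd.read_csv(p, comment="#")
    risk_path = p.with_name(p.stem + "_risk.csv")
    risk = None
    n_total = None
    if risk_path.exists():
        rt = pd.read_csv(risk_path, comment="#")
        risk = rt[["time", "n_at_risk"]].to_numpy(dtype=float)
        n_total = int(risk[0, 1])
    else:
        for line in p.read_text().splitlines():
            if line.startswith("#") and "n_total=" in line:
                n_total = int(line.split("n_total=")[1].strip())
                break
        if n_total is None:
            raise ValueError(f"{p}: no risk table and no '# n_total=' header")
    return DigitizedCurve(
        coords=df[["time", "survival"]].to_numpy(dtype=float),
        risk_table=risk,
        n_total=n_total,
        arm=arm,
        endpoint=endpoint,
    )


def build_model_from_config(config: RunConfig, outdir: Path | None = None) -> CEModel:
    """Assemble the survival layer per the config and wrap it in a model."""
    fits: dict[tuple[str, str], object] = {}
    if config.use_calibrated_weibull:
        return build_model(inputs=config.inputs, settings=config.settings)
    for ep in ENDPOINTS:
        if config.survival_source == "synthetic":
            offset = _SEED_PFS if ep == "pfs" else _SEED_OS
            design = default_trial_design(
                ep, n_per_arm=config.n_per_arm, seed=config.seed + offset
            )
            ipds = generate_ipd(design)
            grid = np.arange(0.0, design.censor_time + 1e-9, 3.0)
            curves = {arm: km_curve(ipds[arm], grid) for arm in ARMS}
        else:
            curves = {
                arm: _read_curve(config.curve_files[ep][arm], arm, ep) for arm in ARMS
            }
        for arm, curve in curves.items():
            ipd = reconstruct(curve)
            bundle = fit_candidates(ipd, config.knot_counts, config.criterion)
            fit = bundle.selected_fit
            logger.info("selected %s for %s/%s (criterion=%s)",
                        bundle.selected, ep, arm, config.criterion)
            if outdir is not None:
                (outdir / f"fit_{ep}_{arm}.json").write_text(fit.to_json())
            fits[(ep, arm)] = fit
    return CEModel(fits=fits, settings=config.settings, inputs=config.inputs)


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write artifacts to the output dir.

    Returns a dict of the in-memory results (model, base case, DSA/PSA
    and scenario tables).  Deterministic for a fixed config and seed.
    """
    from psmcea.scenarios import break_even_price, horizon_sweep, price_sweep, utility_scenario, regional_wtp
    from psmcea.uncertainty import ceac, run_psa, tornado

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"psmcea seed={config.seed} config_sha={config.config_hash()}"
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {}
    try:
        logger.info(header)
        model = build_model_from_config(config, outdir)
        results["model"] = model
        base = model.evaluate()
        results["base_case"] = base
        base_df = pd.DataFrame(
            [
                {
                    "arm": economics.TREATMENT,
                    "total_cost": base.treatment.total_cost,
                    "total_qaly": base.treatment.total_qaly,
                    "delta_cost": base.delta_cost,
                    "delta_qaly": base.delta_qaly,
                    "icer": base.icer,
                },
                {
                    "arm": economics.CONTROL,
                    "total_cost": base.control.total_cost,
                    "total_qaly": base.control.total_qaly,
                    "delta_cost": None,
                    "delta_qaly": None,
                    "icer": None,
                },
            ]
        )
        _write_csv(base_df, outdir / "base_case.csv", header)
        for arm in ARMS:
            _write_csv(model.trace(arm).to_frame(), outdir / f"trace_{arm}.csv", header)

        if config.dsa_enabled:
            tor = tornado(model)
            results["tornado"] = tor
            _write_csv(tor, outdir / "tornado.csv", header)
        if config.psa_enabled:
            psa = run_psa(model, n_iter=config.psa_iterations, seed=config.seed + _SEED_PSA)
            results["psa"] = psa
            _write_csv(psa.scatter_frame(), outdir / "psa_scatter.csv", header)
            wtp_grid = np.linspace(0, 4 * config.inputs.wtp, 81)
            cc = ceac(psa, wtp_grid)
            results["ceac"] = cc
            _write_csv(cc, outdir / "ceac.csv", header)

        sweep = price_sweep(model, config.price_reductions)
        results["price_sweep"] = sweep
        _write_csv(sweep, outdir / "price_sweep.csv", header)
        try:
            results["break_even_price"] = break_even_price(model)
        except ValueError as exc:
            logger.warning("break-even price: %s", exc)
        hs = horizon_sweep(model, config.horizons)
        results["horizon_sweep"] = hs
        _write_csv(hs, outdir / "horizon_sweep.csv", header)
        if config.alt_utilities:
            alt = utility_scenario(model, *config.alt_utilities)
            results["utility_scenario"] = alt
        if config.regional_thresholds:
            reg = regional_wtp(base, config.regional_thresholds)
            results["regional_wtp"] = reg
            _write_csv(reg, outdir / "regional_wtp.csv", header)
        summary = {
            "seed": config.seed,
            "config_sha": config.config_hash(),
            "base_case": base.as_dict(),
            "break_even_price": results.get("break_even_price"),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results
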